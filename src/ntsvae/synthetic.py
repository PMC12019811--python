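"""Synthetic networked-time-series generator and masking schemes.

The generator produces a complete ground truth — smooth, spatially
correlated node signals on a static base graph, and a dynamic weighted graph
obtained by RBF-thresholding those signals on the base edges — and then
hides parts of it:

* node features are hidden i.i.d. with probability ``node_missing_rate``;
* edge weights are hidden by the *endpoint rule* (an edge is unobserved at
  time t whenever either incident node's features are unobserved at t), or
  with a fixed 70% drop probability for such edges, or not at all.

The hidden entries become the held-out evaluation masks, so imputation
quality can be measured against the exact ground truth.  Under the endpoint
rule with feature missing rate p, the expected hidden-edge fraction is
1 - (1-p)^2 (43.75% at p = 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import NTSBundle, save_bundle

__all__ = ["GeneratorConfig", "GroundTruthNTS", "generate_nts",
           "rbf_similarity", "apply_masks", "save_ground_truth"]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    The defaults are the recovery-fixture conditions: a small geometric
    sensor network (N=12) observed for T=200 steps with one signal per node,
    25% of feature entries missing, endpoint-rule edge masking, and dynamics
    threshold k=0.3.
    """

    n_nodes: int = 12
    n_steps: int = 200
    n_features: int = 1
    base_graph: str = "geometric"      # geometric | erdos_renyi | grid
    rank: int = 3                      # number of latent temporal factors
    temporal_smoothness: float = 8.0   # Gaussian smoothing length (steps)
    coupling: float = 0.5              # loading diffusion along base edges
    noise_sd: float = 0.1
    rbf_sigma: float = 1.0
    dynamics_threshold: float = 0.3    # k in the RBF edge-dropping rule
    node_missing_rate: float = 0.25
    edge_rule: str = "endpoint"        # endpoint | drop70 | none
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.node_missing_rate < 1.0):
            raise ValueError("node_missing_rate must be in [0, 1)")
        if self.dynamics_threshold < 0:
            raise ValueError("dynamics_threshold must be >= 0")
        if self.rbf_sigma <= 0:
            raise ValueError("rbf_sigma must be > 0")
        if self.edge_rule not in ("endpoint", "drop70", "none"):
            raise ValueError(f"unknown edge_rule {self.edge_rule!r}")
        if self.base_graph not in ("geometric", "erdos_renyi", "grid"):
            raise ValueError(f"unknown base_graph {self.base_graph!r}")


@dataclass
class GroundTruthNTS:
    """Complete truth plus the partially observed bundle derived from it."""

    features: np.ndarray          # (T, N, D) complete
    adjacency: np.ndarray         # (T, N, N) complete dynamic weights
    bundle: NTSBundle             # partially observed view
    eval_feature_mask: np.ndarray  # 1 where a feature entry was hidden
    eval_edge_mask: np.ndarray     # 1 where an edge entry was hidden
    base_adjacency: np.ndarray = field(default=None)  # static weights


def rbf_similarity(x_u: np.ndarray, x_v: np.ndarray, sigma: float) -> float:
    """exp(-||x_u - x_v||^2 / (2 sigma^2)), in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d2 = float(np.sum((np.asarray(x_u, float) - np.asarray(x_v, float)) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _base_graph(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Static weighted base adjacency (symmetric, zero diagonal)."""
    n = cfg.n_nodes
    if cfg.base_graph == "geometric":
        # sensors scattered in the unit square; thresholded Gaussian kernel
        # of pairwise distance gives the edge weights
        pos = rng.uniform(size=(n, 2))
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        theta = np.median(dist[dist > 0]) * 0.6
        W = np.exp(-(dist**2) / (2 * theta**2))
        W[W < np.exp(-0.5)] = 0.0  # keep edges within ~one kernel length
        np.fill_diagonal(W, 0.0)
    elif cfg.base_graph == "erdos_renyi":
        g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
        W = np.zeros((n, n))
        for u, v in g.edges:
            W[u, v] = W[v, u] = rng.uniform(0.5, 1.5)
    else:  # grid
        side = int(np.ceil(np.sqrt(n)))
        g = nx.grid_2d_graph(side, side)
        mapping = {node: i for i, node in enumerate(sorted(g.nodes))}
        W = np.zeros((n, n))
        for a, b in g.edges:
            i, j = mapping[a], mapping[b]
            if i < n and j < n:
                W[i, j] = W[j, i] = 1.0
    # guarantee no isolated node: connect to the nearest index neighbour
    isolated = np.where(W.sum(axis=1) == 0)[0]
    for u in isolated:
        v = (u + 1) % n
        W[u, v] = W[v, u] = 1.0
    return W


def _signals(cfg: GeneratorConfig, base: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Smooth rank-r factor signals with loadings diffused along base edges."""
    T, n, D = cfg.n_steps, cfg.n_nodes, cfg.n_features
    factors = rng.standard_normal((T, cfg.rank))
    factors = gaussian_filter1d(factors, cfg.temporal_smoothness, axis=0,
                                mode="nearest")
    factors /= factors.std(axis=0, keepdims=True) + 1e-12
    deg = base.sum(axis=1, keepdims=True)
    P = np.divide(base, deg, out=np.zeros_like(base), where=deg > 0)
    X = np.zeros((T, n, D))
    for d in range(D):
        loadings = rng.standard_normal((n, cfg.rank))
        for _ in range(2):  # neighbour coupling: diffuse loadings on the graph
            loadings = (1 - cfg.coupling) * loadings + cfg.coupling * (P @ loadings)
        loadings /= np.linalg.norm(loadings, axis=1, keepdims=True) + 1e-12
        X[:, :, d] = factors @ loadings.T
    X += cfg.noise_sd * rng.standard_normal((T, n, D))
    return X


def _dynamic_adjacency(cfg: GeneratorConfig, base: np.ndarray,
                       X: np.ndarray) -> np.ndarray:
    """Keep a base edge at time t iff the endpoint signals are RBF-similar."""
    T, n = cfg.n_steps, cfg.n_nodes
    A = np.zeros((T, n, n))
    d2 = ((X[:, :, None, :] - X[:, None, :, :]) ** 2).sum(-1)  # (T, N, N)
    sim = np.exp(-d2 / (2.0 * cfg.rbf_sigma**2))
    keep = sim > cfg.dynamics_threshold
    A = np.where(keep & (base > 0)[None, :, :], base[None, :, :], 0.0)
    return A


def apply_masks(features: np.ndarray, adjacency: np.ndarray,
                base: np.ndarray, p: float, edge_rule: str,
                seed: int, timestamps: np.ndarray | None = None,
                ) -> tuple[NTSBundle, np.ndarray, np.ndarray]:
    """Hide entries of a complete NTS; return bundle + evaluation masks.

    Feature entries are hidden i.i.d. with probability ``p``.  Edge slots
    eligible for hiding are the static base-graph edges (u, v) at each t;
    the endpoint rule hides a slot whenever either endpoint has any hidden
    feature at t, the drop70 rule hides such slots with probability 0.7.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError("p must be in [0, 1)")
    T, n, D = features.shape
    rng = np.random.default_rng(seed)
    feature_mask = (rng.uniform(size=(T, n, D)) >= p).astype(float)

    node_observed = feature_mask.min(axis=2)  # (T, N): 1 iff all features seen
    edge_sites = (base > 0)[None, :, :].repeat(T, axis=0)
    endpoint_bad = (node_observed[:, :, None] * node_observed[:, None, :]) == 0
    if edge_rule == "endpoint":
        hidden_edges = edge_sites & endpoint_bad
    elif edge_rule == "drop70":
        iu = np.triu(np.ones((n, n), dtype=bool), k=1)
        coin = rng.uniform(size=(T, n, n)) < 0.7
        coin = np.where(iu[None], coin, np.swapaxes(coin, 1, 2))  # symmetric
        hidden_edges = edge_sites & endpoint_bad & coin
    elif edge_rule == "none":
        hidden_edges = np.zeros_like(edge_sites)
    else:
        raise ValueError(f"unknown edge_rule {edge_rule!r}")

    edge_mask = (~hidden_edges).astype(float)
    obs_features = np.where(feature_mask == 1, features, np.nan)
    obs_adjacency = np.where(edge_mask == 1, adjacency, np.nan)
    if timestamps is None:
        timestamps = np.arange(T, dtype=float)
    bundle = NTSBundle(
        features=obs_features, adjacency=obs_adjacency,
        feature_mask=feature_mask, edge_mask=edge_mask,
        timestamps=timestamps, undirected=True, absent_edges="zero",
    )
    eval_feature_mask = 1.0 - feature_mask
    eval_edge_mask = hidden_edges.astype(float)
    return bundle, eval_feature_mask, eval_edge_mask


def generate_nts(cfg: GeneratorConfig) -> GroundTruthNTS:
    """Sample a complete NTS and its partially observed bundle."""
    rng = np.random.default_rng(cfg.seed)
    base = _base_graph(cfg, rng)
    X = _signals(cfg, base, rng)
    A = _dynamic_adjacency(cfg, base, X)
    mask_seed = int(rng.integers(2**31))
    bundle, eval_fm, eval_em = apply_masks(
        X, A, base, cfg.node_missing_rate, cfg.edge_rule, mask_seed)
    return GroundTruthNTS(
        features=X, adjacency=A, bundle=bundle,
        eval_feature_mask=eval_fm, eval_edge_mask=eval_em,
        base_adjacency=base,
    )


def save_ground_truth(truth: GroundTruthNTS, path: str | Path) -> None:
    """Write the observed bundle plus a truth/ subdirectory with the full data."""
    path = Path(path)
    save_bundle(truth.bundle, path)
    T = truth.features.shape[0]
    full = NTSBundle(
        features=truth.features, adjacency=truth.adjacency,
        feature_mask=np.ones_like(truth.features),
        edge_mask=np.ones_like(truth.adjacency),
        timestamps=truth.bundle.timestamps,
        node_ids=truth.bundle.node_ids,
        feature_names=truth.bundle.feature_names,
    )
    save_bundle(full, path / "truth")
    np.savetxt(path / "truth" / "eval_feature_mask.csv",
               truth.eval_feature_mask.reshape(T, -1), delimiter=",", fmt="%d")
    np.savetxt(path / "truth" / "eval_edge_mask.csv",
               truth.eval_edge_mask.reshape(T, -1), delimiter=",", fmt="%d")


def load_ground_truth(path: str | Path) -> GroundTruthNTS:
    from .core import load_bundle

    path = Path(path)
    bundle = load_bundle(path)
    full = load_bundle(path / "truth")
    T, N, D = full.features.shape
    eval_fm = np.loadtxt(path / "truth" / "eval_feature_mask.csv",
                         delimiter=",").reshape(T, N, D)
    eval_em = np.loadtxt(path / "truth" / "eval_edge_mask.csv",
                         delimiter=",").reshape(T, N, N)
    return GroundTruthNTS(
        features=full.features, adjacency=full.adjacency, bundle=bundle,
        eval_feature_mask=eval_fm, eval_edge_mask=eval_em,
    )
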