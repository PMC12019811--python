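"""Random-walk-with-restart (RWR) node position embeddings.

Each node's position vector collects its RWR (personalized-PageRank) score
against a small set of anchor nodes, one score vector per time step of the
graph sequence.  RWR mixes local neighbourhood mass with long-range
reachability, so the resulting embeddings distinguish nodes that
message-passing (1-WL-bounded) aggregation cannot: on a vertex-transitive
graph such as a cycle, all nodes look identical to colour refinement, but
their RWR scores against a fixed anchor depend on their distance from it.

The walk solves the fixed point r = (1-c) W r + c e_a with W column
stochastic over weighted degree, so every score vector is a probability
distribution; power iteration contracts with factor (1-c) in L1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Window

__all__ = ["AnchorSet", "PositionTensor", "rwr_scores", "select_anchors",
           "build_position_tensor", "default_anchor_count", "transition_matrix"]

DEFAULT_RESTART = 0.15
DEFAULT_TOL = 1e-8
MAX_ITER = 10_000


@dataclass(frozen=True)
class AnchorSet:
    anchor_indices: tuple[int, ...]
    selection_seed: int
    strategy: str  # "degree_top" | "random"

    def __post_init__(self):
        if len(set(self.anchor_indices)) != len(self.anchor_indices):
            raise ValueError("anchor indices must be distinct")
        if len(self.anchor_indices) < 1:
            raise ValueError("need at least one anchor")

    def __len__(self):
        return len(self.anchor_indices)


@dataclass
class PositionTensor:
    """RWR scores of every node against every anchor, per time step: (T, N, L)."""

    scores: np.ndarray
    anchors: AnchorSet
    restart_prob: float
    tolerance: float


def default_anchor_count(n_nodes: int) -> int:
    """min(N, ceil(log2 N)^2) — the anchor-set sizing of position-aware GNNs."""
    if n_nodes <= 1:
        return n_nodes
    return min(n_nodes, int(np.ceil(np.log2(n_nodes)) ** 2))


def transition_matrix(adjacency: np.ndarray, anchor: int) -> np.ndarray:
    """Column-stochastic walk matrix; dangling columns restart to the anchor."""
    A = np.asarray(adjacency, dtype=np.float64)
    n = A.shape[0]
    deg = A.sum(axis=0)  # weighted degree of each source column
    W = np.zeros_like(A)
    nz = deg > 0
    W[:, nz] = A[:, nz] / deg[nz]
    W[anchor, ~nz] = 1.0
    return W


def rwr_scores(adjacency: np.ndarray, anchor: int, c: float = DEFAULT_RESTART,
               tol: float = DEFAULT_TOL) -> np.ndarray:
    """Power-iterate r = (1-c) W r + c e_anchor to the unique fixed point."""
    if not (0.0 < c <= 1.0):
        raise ValueError(f"restart probability must be in (0, 1], got {c}")
    A = np.asarray(adjacency, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    n = A.shape[0]
    if not (0 <= anchor < n):
        raise IndexError(f"anchor {anchor} out of range for {n} nodes")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    e = np.zeros(n)
    e[anchor] = 1.0
    if c == 1.0:
        return e
    W = transition_matrix(A, anchor)
    r = e.copy()
    for _ in range(MAX_ITER):
        r_next = (1.0 - c) * (W @ r) + c * e
        if np.max(np.abs(r_next - r)) < tol:
            return r_next
        r = r_next
    raise RuntimeError(f"RWR power iteration did not converge within {MAX_ITER} steps")


def _observed_adjacency(window: Window, t: int) -> np.ndarray:
    """Adjacency at step t with unobserved entries treated as weight 0."""
    b = window.bundle
    A = np.where(b.edge_mask[t] == 1, b.adjacency[t], 0.0)
    return np.nan_to_num(A, nan=0.0)


def select_anchors(window: Window, count: int, strategy: str = "degree_top",
                   seed: int = 0) -> AnchorSet:
    """Pick anchors by total observed weighted degree or uniformly at random."""
    n = window.bundle.n_nodes
    if not (1 <= count <= n):
        raise ValueError(f"anchor count {count} not in [1, {n}]")
    if strategy == "degree_top":
        degree = np.zeros(n)
        for t in range(window.length):
            degree += _observed_adjacency(window, t).sum(axis=1)
        # sort by (-degree, index): ties broken toward the smaller index
        order = np.lexsort((np.arange(n), -degree))
        idx = tuple(int(i) for i in sorted(order[:count]))
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        idx = tuple(int(i) for i in sorted(rng.choice(n, size=count, replace=False)))
    else:
        raise ValueError(f"unknown anchor strategy {strategy!r}")
    return AnchorSet(idx, seed, strategy)


def _rwr_all_anchors(A: np.ndarray, anchor_idx: tuple[int, ...], c: float,
                     tol: float) -> np.ndarray:
    """Joint power iteration over all anchors (columns of the output).

    Dangling columns of the walk matrix restart to the respective anchor;
    this is expressed as W0 (dangling columns zeroed) plus the dangling
    probability mass redirected onto the anchor's coordinate, so a single
    (N, N) @ (N, L) product advances every anchor at once.
    """
    n = A.shape[0]
    L = len(anchor_idx)
    E = np.zeros((n, L))
    E[list(anchor_idx), np.arange(L)] = 1.0
    if c == 1.0:
        return E
    deg = A.sum(axis=0)
    nz = deg > 0
    W0 = np.zeros_like(A)
    W0[:, nz] = A[:, nz] / deg[nz]
    dangling = ~nz
    R = E.copy()
    for _ in range(MAX_ITER):
        mass = R[dangling].sum(axis=0)  # per-anchor dangling mass -> anchor
        R_next = (1.0 - c) * (W0 @ R + E * mass) + c * E
        if np.max(np.abs(R_next - R)) < tol:
            return R_next
        R = R_next
    raise RuntimeError(f"RWR power iteration did not converge within {MAX_ITER} steps")


def build_position_tensor(window: Window, anchors: AnchorSet,
                          c: float = DEFAULT_RESTART,
                          tol: float = DEFAULT_TOL) -> PositionTensor:
    """RWR scores of all nodes against each anchor for every step of a window."""
    if not (0.0 < c <= 1.0):
        raise ValueError(f"restart probability must be in (0, 1], got {c}")
    n = window.bundle.n_nodes
    if any(not (0 <= a < n) for a in anchors.anchor_indices):
        raise IndexError("anchor index out of range for this window")
    T, L = window.length, len(anchors)
    scores = np.zeros((T, n, L))
    for t in range(T):
        A = _observed_adjacency(window, t)
        scores[t] = _rwr_all_anchors(A, anchors.anchor_indices, c, tol)
    return PositionTensor(scores, anchors, c, tol)
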