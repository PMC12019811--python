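"""Data model, validation, windowing and on-disk layout for partially
observed networked time series (NTS).

An NTS couples a multivariate time series (T time steps, N nodes, D features)
with a sequence of weighted graphs on the same nodes.  Both the node features
and the edge weights may be missing; binary masks (1 = observed, 0 = missing)
record which entries are trustworthy.  Values stored under mask = 0 are
sentinels (typically NaN) and must never influence any computation.

On disk a bundle is a directory of plain CSV tables plus a JSON manifest:

    manifest.json     T, N, D, node_ids, feature_names, undirected,
                      absent_edges ("zero" | "missing")
    features.csv      t, node, feature, value      (observed entries)
    feature_mask.csv  t, node, feature, mask       (full table)
    edges.csv         t, u, v, weight              (observed entries)
    edge_mask.csv     t, u, v, mask                (entries that deviate from
                                                    the absent-edge default)
    timestamps.csv    t, timestamp
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["NTSBundle", "Window", "ValidationCheck", "ValidationReport",
           "load_bundle", "save_bundle", "make_windows", "validate"]


class BundleFormatError(ValueError):
    """Malformed manifest or table layout."""


class BundleValidationError(ValueError):
    """Bundle contents violate an NTS invariant."""


@dataclass
class NTSBundle:
    """A partially observed networked time series.

    features : (T, N, D) float array, NaN allowed where feature_mask == 0
    adjacency : (T, N, N) nonnegative weights, zero diagonal
    feature_mask / edge_mask : binary, 1 = observed
    timestamps : strictly increasing, length T
    """

    features: np.ndarray
    adjacency: np.ndarray
    feature_mask: np.ndarray
    edge_mask: np.ndarray
    timestamps: np.ndarray
    node_ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    undirected: bool = True
    absent_edges: str = "zero"

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.feature_mask = np.asarray(self.feature_mask, dtype=np.float64)
        self.edge_mask = np.asarray(self.edge_mask, dtype=np.float64)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if not self.node_ids:
            self.node_ids = [f"n{i}" for i in range(self.n_nodes)]
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.n_features)]

    @property
    def n_steps(self) -> int:
        return self.features.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.features.shape[1]

    @property
    def n_features(self) -> int:
        return self.features.shape[2]

    def check_shapes(self) -> None:
        T, N, D = self.features.shape
        if self.feature_mask.shape != (T, N, D):
            raise BundleValidationError(
                f"feature_mask shape {self.feature_mask.shape} != {(T, N, D)}")
        if self.adjacency.shape != (T, N, N):
            raise BundleValidationError(
                f"adjacency shape {self.adjacency.shape} != {(T, N, N)}")
        if self.edge_mask.shape != (T, N, N):
            raise BundleValidationError(
                f"edge_mask shape {self.edge_mask.shape} != {(T, N, N)}")
        if self.timestamps.shape != (T,):
            raise BundleValidationError(
                f"timestamps shape {self.timestamps.shape} != {(T,)}")
        if len(self.node_ids) != N or len(self.feature_names) != D:
            raise BundleValidationError("node_ids/feature_names length mismatch")

    def slice_steps(self, start: int, stop: int) -> "NTSBundle":
        return replace(
            self,
            features=self.features[start:stop],
            adjacency=self.adjacency[start:stop],
            feature_mask=self.feature_mask[start:stop],
            edge_mask=self.edge_mask[start:stop],
            timestamps=self.timestamps[start:stop],
        )


@dataclass
class Window:
    """A contiguous slice of a bundle: steps ``start .. start+length-1``."""

    bundle: NTSBundle
    start: int
    length: int

    def __post_init__(self):
        if not (1 <= self.length):
            raise ValueError("window length must be >= 1")


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    n_offenders: int


@dataclass
class ValidationReport:
    checks: list[ValidationCheck]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def __getitem__(self, name: str) -> ValidationCheck:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def validate(bundle: NTSBundle) -> ValidationReport:
    """Check every NTS invariant; report offender counts, never raise."""
    checks: list[ValidationCheck] = []
    fm, em = bundle.feature_mask, bundle.edge_mask
    X, A = bundle.features, bundle.adjacency

    def add(name, n_bad):
        checks.append(ValidationCheck(name, int(n_bad) == 0, int(n_bad)))

    add("feature_mask_binary", np.count_nonzero(~np.isin(fm, (0.0, 1.0))))
    add("edge_mask_binary", np.count_nonzero(~np.isin(em, (0.0, 1.0))))
    add("observed_features_finite",
        np.count_nonzero((fm == 1) & ~np.isfinite(X)))
    obs_edges = em == 1
    add("observed_edges_finite",
        np.count_nonzero(obs_edges & ~np.isfinite(A)))
    finite_obs = obs_edges & np.isfinite(A)
    add("observed_edges_nonnegative",
        np.count_nonzero(finite_obs & (A < 0)))
    diag = np.einsum("tii->ti", A)
    add("zero_diagonal", np.count_nonzero(diag != 0))
    add("timestamps_increasing",
        np.count_nonzero(np.diff(bundle.timestamps) <= 0))
    if bundle.undirected:
        AT = np.swapaxes(A, 1, 2)
        mT = np.swapaxes(em, 1, 2)
        both = obs_edges & (mT == 1) & np.isfinite(A) & np.isfinite(AT)
        bad = np.count_nonzero(both & (A != AT))
        add("symmetric_weights", bad)
        add("symmetric_masks", np.count_nonzero(em != mT))
    return ValidationReport(checks)


def make_windows(bundle: NTSBundle, length: int, stride: int) -> list[Window]:
    """Sliding windows of ``length`` steps; floor((T-length)/stride)+1 of them."""
    if length < 1 or stride < 1:
        raise ValueError("length and stride must be positive")
    T = bundle.n_steps
    if length > T:
        raise ValueError(f"window length {length} exceeds series length {T}")
    starts = range(0, T - length + 1, stride)
    return [Window(bundle.slice_steps(s, s + length), s, length) for s in starts]


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

_MANIFEST_FIELDS = ("T", "N", "D", "node_ids", "feature_names",
                    "undirected", "absent_edges")


def save_bundle(bundle: NTSBundle, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.check_shapes()
    T, N, D = bundle.features.shape
    manifest = {
        "T": T, "N": N, "D": D,
        "node_ids": list(bundle.node_ids),
        "feature_names": list(bundle.feature_names),
        "undirected": bool(bundle.undirected),
        "absent_edges": bundle.absent_edges,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    t_idx, n_idx, d_idx = np.nonzero(bundle.feature_mask == 1)
    pd.DataFrame({
        "t": t_idx, "node": n_idx, "feature": d_idx,
        "value": bundle.features[t_idx, n_idx, d_idx],
    }).to_csv(path / "features.csv", index=False, float_format="%.17g")

    tm, nm, dm = np.indices(bundle.feature_mask.shape)
    pd.DataFrame({
        "t": tm.ravel(), "node": nm.ravel(), "feature": dm.ravel(),
        "mask": bundle.feature_mask.ravel().astype(int),
    }).to_csv(path / "feature_mask.csv", index=False)

    # observed edges: store nonzero weights (upper triangle if undirected)
    em = bundle.edge_mask.copy()
    A = bundle.adjacency
    if bundle.undirected:
        iu = np.triu(np.ones((N, N), dtype=bool), k=1)
        sel = (em == 1) & iu[None, :, :]
    else:
        off = ~np.eye(N, dtype=bool)
        sel = (em == 1) & off[None, :, :]
    nz = sel & (A != 0) & np.isfinite(A)
    te, ue, ve = np.nonzero(nz)
    pd.DataFrame({
        "t": te, "u": ue, "v": ve, "weight": A[te, ue, ve],
    }).to_csv(path / "edges.csv", index=False, float_format="%.17g")

    # edge-mask rows: entries that deviate from the absent-edge default
    off_diag = ~np.eye(N, dtype=bool)
    if bundle.absent_edges == "zero":
        deviant = (em == 0) & off_diag[None, :, :]
        mask_val = 0
    else:  # absent=missing: record observed-zero entries not in edges.csv
        deviant = (em == 1) & (((A == 0) | ~np.isfinite(A))) & off_diag[None, :, :]
        mask_val = 1
    if bundle.undirected:
        iu = np.triu(np.ones((N, N), dtype=bool), k=1)
        deviant = deviant & iu[None, :, :]
    td, ud, vd = np.nonzero(deviant)
    pd.DataFrame({
        "t": td, "u": ud, "v": vd, "mask": mask_val,
    }).to_csv(path / "edge_mask.csv", index=False)

    pd.DataFrame({
        "t": np.arange(T), "timestamp": bundle.timestamps,
    }).to_csv(path / "timestamps.csv", index=False, float_format="%.17g")


def load_bundle(path: str | Path) -> NTSBundle:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise BundleFormatError(f"missing manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    for key in _MANIFEST_FIELDS:
        if key not in manifest:
            raise BundleFormatError(f"manifest.json missing field '{key}'")
    T, N, D = int(manifest["T"]), int(manifest["N"]), int(manifest["D"])
    undirected = bool(manifest["undirected"])
    absent = manifest["absent_edges"]
    if absent not in ("zero", "missing"):
        raise BundleFormatError(
            f"manifest field 'absent_edges' must be 'zero' or 'missing', got {absent!r}")

    features = np.full((T, N, D), np.nan)
    feature_mask = np.zeros((T, N, D))
    ftab = pd.read_csv(path / "features.csv", float_precision="round_trip")
    _check_bounds(ftab, {"t": T, "node": N, "feature": D}, "features.csv")
    features[ftab["t"], ftab["node"], ftab["feature"]] = ftab["value"]
    feature_mask[ftab["t"], ftab["node"], ftab["feature"]] = 1

    fmask_path = path / "feature_mask.csv"
    if fmask_path.exists():
        mtab = pd.read_csv(fmask_path)
        _check_bounds(mtab, {"t": T, "node": N, "feature": D}, "feature_mask.csv")
        feature_mask[mtab["t"], mtab["node"], mtab["feature"]] = mtab["mask"]

    if absent == "zero":
        adjacency = np.zeros((T, N, N))
        edge_mask = np.ones((T, N, N))
    else:
        adjacency = np.full((T, N, N), np.nan)
        edge_mask = np.zeros((T, N, N))
    # diagonal: structurally zero and observed
    di = np.arange(N)
    adjacency[:, di, di] = 0.0
    edge_mask[:, di, di] = 1.0

    etab = pd.read_csv(path / "edges.csv", float_precision="round_trip")
    _check_bounds(etab, {"t": T, "u": N, "v": N}, "edges.csv")
    if (etab["weight"] < 0).any():
        raise BundleValidationError("edges.csv contains negative weights")
    adjacency[etab["t"], etab["u"], etab["v"]] = etab["weight"]
    edge_mask[etab["t"], etab["u"], etab["v"]] = 1
    if undirected:
        adjacency[etab["t"], etab["v"], etab["u"]] = etab["weight"]
        edge_mask[etab["t"], etab["v"], etab["u"]] = 1

    emask_path = path / "edge_mask.csv"
    if emask_path.exists():
        ktab = pd.read_csv(emask_path)
        _check_bounds(ktab, {"t": T, "u": N, "v": N}, "edge_mask.csv")
        tt = ktab["t"].to_numpy(dtype=int)
        uu = ktab["u"].to_numpy(dtype=int)
        vv = ktab["v"].to_numpy(dtype=int)
        mm = ktab["mask"].to_numpy(dtype=float)
        endpoint_pairs = [(uu, vv)] + ([(vv, uu)] if undirected else [])
        for a, b in endpoint_pairs:
            edge_mask[tt, a, b] = mm
            miss = mm == 0
            adjacency[tt[miss], a[miss], b[miss]] = np.nan
            obs = mm == 1
            cur = adjacency[tt[obs], a[obs], b[obs]]
            adjacency[tt[obs], a[obs], b[obs]] = np.nan_to_num(cur, nan=0.0)

    ttab = pd.read_csv(path / "timestamps.csv", float_precision="round_trip")
    timestamps = np.zeros(T)
    timestamps[ttab["t"].to_numpy(dtype=int)] = ttab["timestamp"]

    bundle = NTSBundle(
        features=features, adjacency=adjacency,
        feature_mask=feature_mask, edge_mask=edge_mask,
        timestamps=timestamps,
        node_ids=[str(s) for s in manifest["node_ids"]],
        feature_names=[str(s) for s in manifest["feature_names"]],
        undirected=undirected, absent_edges=absent,
    )
    bundle.check_shapes()
    report = validate(bundle)
    if not report.ok:
        bad = [c.name for c in report.checks if not c.passed]
        raise BundleValidationError(f"bundle fails invariants: {bad}")
    return bundle


def _check_bounds(tab: pd.DataFrame, limits: dict[str, int], name: str) -> None:
    for col, limit in limits.items():
        if col not in tab.columns:
            raise BundleFormatError(f"{name} missing column '{col}'")
        if len(tab) and ((tab[col] < 0).any() or (tab[col] >= limit).any()):
            raise BundleValidationError(
                f"{name}: column '{col}' out of range [0, {limit})")
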