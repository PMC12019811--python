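"""Masked imputation metrics and the mean-imputation baseline.

Metrics are computed only at held-out evaluation entries (the entries the
masking scheme deliberately hid), never at entries the model saw:

* MAE, MSE over evaluated feature entries;
* MRE = sum |error| / sum |label| over evaluated feature entries;
* the Frobenius norm of the adjacency error over evaluated edge slots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NTSBundle

__all__ = ["ImputationMetrics", "evaluate", "mean_baseline"]


@dataclass
class ImputationMetrics:
    mae: float
    mse: float
    mre: float
    link_frobenius: float
    n_eval_feature_entries: int
    n_eval_edge_entries: int

    def as_dict(self) -> dict:
        return {
            "mae": self.mae, "mse": self.mse, "mre": self.mre,
            "link_frobenius": self.link_frobenius,
            "n_eval_feature_entries": self.n_eval_feature_entries,
            "n_eval_edge_entries": self.n_eval_edge_entries,
        }


def evaluate(filled_features: np.ndarray, filled_adjacency: np.ndarray,
             true_features: np.ndarray, true_adjacency: np.ndarray,
             eval_feature_mask: np.ndarray, eval_edge_mask: np.ndarray,
             obs_feature_mask: np.ndarray | None = None,
             obs_edge_mask: np.ndarray | None = None) -> ImputationMetrics:
    """Score imputed values against ground truth at held-out entries only."""
    eval_fm = np.asarray(eval_feature_mask, float)
    eval_em = np.asarray(eval_edge_mask, float)
    if obs_feature_mask is not None and np.any(
            (eval_fm == 1) & (np.asarray(obs_feature_mask) == 1)):
        raise ValueError("evaluation mask overlaps the observation mask (features)")
    if obs_edge_mask is not None and np.any(
            (eval_em == 1) & (np.asarray(obs_edge_mask) == 1)):
        raise ValueError("evaluation mask overlaps the observation mask (edges)")

    sel = eval_fm == 1
    err = np.asarray(true_features, float)[sel] - np.asarray(filled_features, float)[sel]
    labels = np.asarray(true_features, float)[sel]
    n_feat = int(sel.sum())
    if n_feat:
        mae = float(np.abs(err).mean())
        mse = float((err**2).mean())
        denom = float(np.abs(labels).sum())
        mre = float(np.abs(err).sum() / denom) if denom > 0 else 0.0
    else:
        mae = mse = mre = 0.0

    esel = eval_em == 1
    n_edge = int(esel.sum())
    ediff = (np.asarray(true_adjacency, float)[esel]
             - np.asarray(filled_adjacency, float)[esel])
    link = float(np.sqrt((ediff**2).sum())) if n_edge else 0.0
    return ImputationMetrics(mae, mse, mre, link, n_feat, n_edge)


def mean_baseline(bundle: NTSBundle) -> np.ndarray:
    """Fill each missing entry with the node's observed mean of that feature.

    A node-feature with no observations at all falls back to the global
    observed mean of the feature (0 if the feature is never observed).
    """
    X = np.asarray(bundle.features, float)
    M = np.asarray(bundle.feature_mask, float)
    masked = np.where(M == 1, np.nan_to_num(X, nan=0.0), 0.0)
    counts = M.sum(axis=0)                      # (N, D)
    sums = masked.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        node_means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    global_counts = counts.sum(axis=0)          # (D,)
    global_means = np.where(global_counts > 0,
                            sums.sum(axis=0) / np.maximum(global_counts, 1), 0.0)
    fill = np.where(np.isnan(node_means), global_means[None, :], node_means)
    return np.where(M == 1, X, fill[None, :, :])
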