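"""Loss assembly, the optimization loop, and the end-to-end impute entry point.

The training loss is the multi-task objective of the model: a masked MAE on
the final bidirectional imputation, masked MAEs on the raw first- and
third-stage predictions of both directions, a per-entry-normalized Frobenius
error between predicted and observed adjacencies (weight gamma), and the
closed-form KL divergence of each direction's Gaussian posterior from the
standard normal (weight beta).  All feature terms are evaluated at observed
entries only — values stored under mask = 0 never touch the loss.

Feature series are standardized per feature over observed entries before
training; the scaler is stored in the checkpoint and inverted at impute
time.  Observed entries of the imputed output are copied from the input
verbatim, for any parameters, trained or not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack
from .core import NTSBundle, Window, make_windows, validate
from .model import BiVAEImputer, ModelConfig
from .nn import Adam
from .positions import (build_position_tensor, default_anchor_count,
                        select_anchors)

__all__ = ["LossBreakdown", "TrainConfig", "masked_mae", "link_frobenius",
           "compute_loss", "train", "impute", "FeatureScaler"]


@dataclass
class LossBreakdown:
    """The nine additive loss terms and their weighted total."""

    final_mae: float
    kl_f: float
    kl_b: float
    stage1_mae_f: float
    stage1_mae_b: float
    link_frob_f: float
    link_frob_b: float
    stage3_mae_f: float
    stage3_mae_b: float
    beta: float
    gamma: float

    @property
    def total(self) -> float:
        return (self.final_mae
                + self.beta * (self.kl_f + self.kl_b)
                + self.stage1_mae_f + self.stage1_mae_b
                + self.gamma * (self.link_frob_f + self.link_frob_b)
                + self.stage3_mae_f + self.stage3_mae_b)


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-3
    batch: int | None = None          # windows per optimizer step; None = all
    window: int = 24
    stride: int = 24
    beta: float = 0.05
    gamma: float = 1.0
    seed: int = 0
    patience: int | None = None       # early stop on training total

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be >= 0")


def masked_mae(pred, label, mask):
    """Sum of masked absolute errors over the masked count (0 if none)."""
    if isinstance(pred, Tensor):
        label_arr = np.nan_to_num(np.asarray(label, float), nan=0.0)
        mask_arr = np.asarray(mask, float)
        if pred.shape != label_arr.shape or pred.shape != mask_arr.shape:
            raise ValueError("masked_mae operands must share one shape")
        denom = max(float(mask_arr.sum()), 1.0)
        return ((Tensor(label_arr) - pred).abs() * Tensor(mask_arr)).sum() / denom
    pred, label, mask = (np.asarray(a, float) for a in (pred, label, mask))
    if pred.shape != label.shape or pred.shape != mask.shape:
        raise ValueError("masked_mae operands must share one shape")
    err = np.abs(np.nan_to_num(label, nan=0.0) - np.nan_to_num(pred, nan=0.0))
    return float((mask * err).sum() / max(mask.sum(), 1.0))


def link_frobenius(pred_adj, obs_adj, edge_mask):
    """sqrt(sum of masked squared errors) — the raw Frobenius aggregate."""
    if isinstance(pred_adj, Tensor):
        obs = np.nan_to_num(np.asarray(obs_adj, float), nan=0.0)
        mask = np.asarray(edge_mask, float)
        if pred_adj.shape != obs.shape or pred_adj.shape != mask.shape:
            raise ValueError("link_frobenius operands must share one shape")
        sq = ((Tensor(obs) - pred_adj) ** 2.0) * Tensor(mask)
        return (sq.sum() + 1e-30).sqrt()
    pred, obs, mask = (np.asarray(a, float)
                       for a in (pred_adj, obs_adj, edge_mask))
    if pred.shape != obs.shape or pred.shape != mask.shape:
        raise ValueError("link_frobenius operands must share one shape")
    diff = np.nan_to_num(obs, nan=0.0) - np.nan_to_num(pred, nan=0.0)
    return float(np.sqrt((mask * diff**2).sum()))


def _kl_divergence(mean: Tensor, logvar: Tensor) -> Tensor:
    """KL(N(mean, diag exp(logvar)) || N(0, I)), averaged per element."""
    term = 1.0 + logvar - mean**2.0 - logvar.exp()
    return term.sum() * (-0.5 / mean.data.size)


def _link_rms(pred: Tensor, obs: np.ndarray, mask: np.ndarray) -> Tensor:
    """Per-entry-normalized Frobenius error: RMS over observed edge slots."""
    count = max(float(mask.sum()), 1.0)
    obs = np.nan_to_num(np.asarray(obs, float), nan=0.0)
    sq = ((Tensor(obs) - pred) ** 2.0) * Tensor(mask)
    return (sq.sum() / count + 1e-30).sqrt()


def _loss_tensor(outputs: dict, labels_x: np.ndarray, mask_x: np.ndarray,
                 labels_a: np.ndarray, mask_a: np.ndarray,
                 beta: float, gamma: float) -> tuple[Tensor, LossBreakdown]:
    """Assemble the total loss Tensor and its float breakdown.

    labels/masks are window arrays in forward time: features (B, T, N, D)
    with observation mask, adjacency (B, T, N, N) with edge mask.
    """
    if beta < 0 or gamma < 0:
        raise ValueError("beta and gamma must be >= 0")

    def stack_steps(states, key):
        return stack([s[key] for s in states], axis=1)  # (B, T, ...)

    merged = stack(outputs["merged"], axis=1)
    y1_f = stack_steps(outputs["forward"], "y1")
    y1_b = stack_steps(outputs["backward"], "y1")
    y2_f = stack_steps(outputs["forward"], "y2")
    y2_b = stack_steps(outputs["backward"], "y2")
    a_f = stack_steps(outputs["forward"], "a_out")
    a_b = stack_steps(outputs["backward"], "a_out")

    final_mae = masked_mae(merged, labels_x, mask_x)
    s1f = masked_mae(y1_f, labels_x, mask_x)
    s1b = masked_mae(y1_b, labels_x, mask_x)
    s3f = masked_mae(y2_f, labels_x, mask_x)
    s3b = masked_mae(y2_b, labels_x, mask_x)
    lff = _link_rms(a_f, labels_a, mask_a)
    lfb = _link_rms(a_b, labels_a, mask_a)
    klf = _kl_divergence(outputs["latent_f"].mean, outputs["latent_f"].log_variance)
    klb = _kl_divergence(outputs["latent_b"].mean, outputs["latent_b"].log_variance)

    total = (final_mae + beta * (klf + klb) + s1f + s1b
             + gamma * (lff + lfb) + s3f + s3b)
    breakdown = LossBreakdown(
        final_mae=final_mae.item(), kl_f=klf.item(), kl_b=klb.item(),
        stage1_mae_f=s1f.item(), stage1_mae_b=s1b.item(),
        link_frob_f=lff.item(), link_frob_b=lfb.item(),
        stage3_mae_f=s3f.item(), stage3_mae_b=s3b.item(),
        beta=beta, gamma=gamma,
    )
    return total, breakdown


def compute_loss(outputs: dict, labels_x: np.ndarray, mask_x: np.ndarray,
                 labels_a: np.ndarray, mask_a: np.ndarray,
                 beta: float, gamma: float) -> LossBreakdown:
    """Public loss assembly; see ``LossBreakdown.total`` for the invariant."""
    _, breakdown = _loss_tensor(outputs, labels_x, mask_x, labels_a, mask_a,
                                beta, gamma)
    return breakdown


@dataclass
class FeatureScaler:
    """Per-feature standardization fitted on observed entries only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, features: np.ndarray, mask: np.ndarray) -> "FeatureScaler":
        D = features.shape[-1]
        mean = np.zeros(D)
        std = np.ones(D)
        for d in range(D):
            vals = features[..., d][mask[..., d] == 1]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                mean[d] = vals.mean()
                s = vals.std()
                std[d] = s if s > 1e-12 else 1.0
        return cls(mean, std)

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (features - self.mean) / self.std

    def inverse(self, features: np.ndarray) -> np.ndarray:
        return features * self.std + self.mean


def _window_arrays(windows: list[Window], scaler: FeatureScaler,
                   positions: np.ndarray):
    """Stack a list of equal-length windows into batched arrays."""
    xs, ms, rs, as_, ems, ts = [], [], [], [], [], []
    for w in windows:
        b = w.bundle
        xs.append(scaler.transform(np.nan_to_num(b.features, nan=0.0))
                  * b.feature_mask)
        ms.append(b.feature_mask)
        rs.append(positions[w.start:w.start + w.length])
        as_.append(np.nan_to_num(b.adjacency, nan=0.0) * b.edge_mask)
        ems.append(b.edge_mask)
        ts.append(b.timestamps)
    return (np.stack(xs), np.stack(ms), np.stack(rs), np.stack(as_),
            np.stack(ems), np.stack(ts))


def _prepare(bundle: NTSBundle, mcfg: ModelConfig):
    """Anchors + full-series position tensor (computed once, before training)."""
    report = validate(bundle)
    if not report.ok:
        bad = [c.name for c in report.checks if not c.passed]
        raise ValueError(f"bundle fails invariants: {bad}")
    full = Window(bundle, 0, bundle.n_steps)
    L = mcfg.n_anchors or default_anchor_count(bundle.n_nodes)
    anchors = select_anchors(full, L, "degree_top", mcfg.seed)
    positions = build_position_tensor(full, anchors, mcfg.restart_prob).scores
    return anchors, positions


def train(bundle: NTSBundle, mcfg: ModelConfig, tcfg: TrainConfig,
          ) -> tuple[BiVAEImputer, FeatureScaler, list[LossBreakdown]]:
    """Optimize the model on the observed entries of one bundle."""
    anchors, positions = _prepare(bundle, mcfg)
    scaler = FeatureScaler.fit(bundle.features, bundle.feature_mask)
    model = BiVAEImputer(bundle.n_nodes, bundle.n_features, len(anchors), mcfg)
    windows = make_windows(bundle, tcfg.window, tcfg.stride)
    if not windows:
        raise ValueError("no training windows")
    xs, ms, rs, as_, ems, ts = _window_arrays(windows, scaler, positions)
    n_win = xs.shape[0]
    batch = tcfg.batch or n_win
    optimizer = Adam(model.parameters(), lr=tcfg.learning_rate)
    root = np.random.SeedSequence(tcfg.seed)
    log: list[LossBreakdown] = []
    best_total = np.inf
    stall = 0
    for epoch in range(tcfg.epochs):
        epoch_rng = np.random.default_rng(root.spawn(1)[0])
        totals = []
        breakdowns = []
        for lo in range(0, n_win, batch):
            hi = min(lo + batch, n_win)
            try:
                outputs = model.run_bidirectional(
                    xs[lo:hi], ms[lo:hi], rs[lo:hi], ts[lo:hi],
                    rng_f=epoch_rng, rng_b=epoch_rng)
            except FloatingPointError as exc:
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: {exc}") from exc
            total, breakdown = _loss_tensor(
                outputs, xs[lo:hi], ms[lo:hi], as_[lo:hi], ems[lo:hi],
                tcfg.beta, tcfg.gamma)
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"training loss diverged at epoch {epoch}")
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            totals.append(total.item())
            breakdowns.append(breakdown)
        log.append(_average_breakdowns(breakdowns))
        epoch_total = float(np.mean(totals))
        if tcfg.patience is not None:
            if epoch_total < best_total - 1e-9:
                best_total = epoch_total
                stall = 0
            else:
                stall += 1
                if stall > tcfg.patience:
                    break
    return model, scaler, log


def _average_breakdowns(breakdowns: list[LossBreakdown]) -> LossBreakdown:
    fields = ("final_mae", "kl_f", "kl_b", "stage1_mae_f", "stage1_mae_b",
              "link_frob_f", "link_frob_b", "stage3_mae_f", "stage3_mae_b")
    mean = {f: float(np.mean([getattr(b, f) for b in breakdowns]))
            for f in fields}
    return LossBreakdown(beta=breakdowns[0].beta, gamma=breakdowns[0].gamma,
                         **mean)


def impute(bundle: NTSBundle, model: BiVAEImputer, scaler: FeatureScaler,
           window: int, stride: int,
           positions: np.ndarray | None = None,
           ) -> tuple[np.ndarray, np.ndarray]:
    """Fill every missing entry; observed entries are copied exactly.

    Overlapping window predictions at a missing entry are averaged; the
    filled adjacency averages the two directions, is symmetrized for
    undirected bundles and keeps a zero diagonal.
    """
    if model.n_nodes != bundle.n_nodes or model.n_features != bundle.n_features:
        raise ValueError("checkpoint dimensions do not match bundle")
    T, N, D = bundle.features.shape
    if positions is None:
        _, positions = _prepare(bundle, model.cfg)
    if positions.shape[-1] != model.n_anchors:
        raise ValueError("position tensor anchor count does not match checkpoint")
    window = min(window, T)
    starts = list(range(0, T - window + 1, stride))
    if starts[-1] != T - window:
        starts.append(T - window)
    windows = [Window(bundle.slice_steps(s, s + window), s, window)
               for s in starts]
    xs, ms, rs, _, _, ts = _window_arrays(windows, scaler, positions)

    feat_sum = np.zeros((T, N, D))
    feat_cnt = np.zeros((T, N, 1))
    adj_sum = np.zeros((T, N, N))
    adj_cnt = np.zeros((T, 1, 1))
    outputs = model.run_bidirectional(xs, ms, rs, ts,
                                      rng_f=None, rng_b=None)
    for i, w in enumerate(windows):
        for step in range(window):
            t = w.start + step
            feat_sum[t] += outputs["merged"][step].data[i]
            feat_cnt[t] += 1.0
            a_step = 0.5 * (outputs["forward"][step]["a_out"].data[i]
                            + outputs["backward"][step]["a_out"].data[i])
            adj_sum[t] += a_step
            adj_cnt[t] += 1.0

    pred_x = scaler.inverse(feat_sum / feat_cnt)
    pred_a = adj_sum / adj_cnt
    if bundle.undirected:
        pred_a = 0.5 * (pred_a + np.swapaxes(pred_a, 1, 2))
    di = np.arange(N)
    pred_a[:, di, di] = 0.0

    filled_x = np.where(bundle.feature_mask == 1, bundle.features, pred_x)
    filled_a = np.where(bundle.edge_mask == 1,
                        np.nan_to_num(bundle.adjacency, nan=0.0), pred_a)
    return filled_x, filled_a
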