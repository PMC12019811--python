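"""Bidirectional variational autoencoder for networked-time-series imputation.

Architecture, per direction (forward = natural time order, backward = the
time-reversed sequence with its own parameters):

* **Encoder** — a 2-layer GRU over time.  Per node and step the input is the
  observed features (zero-filled at missing entries), the feature mask, and
  the RWR position embedding.  The final hidden state maps through two
  linear heads to the mean and log-variance of a diagonal-Gaussian posterior
  over a per-node latent ``z``; sampling uses seeded reparameterization.

* **Decoder** — unrolled per step with three prediction stages:

  1. a linear map of the previous hidden state gives an initial feature
     prediction; the *filler* keeps observed entries and inserts the
     prediction only where the mask is 0;
  2. node link-embeddings (linear map of [filled features ‖ mask ‖ position
     ‖ previous hidden], concatenated with a unit-norm Bochner time
     encoding, through a two-layer MLP) are scored pairwise by inner
     product, passed through softplus, diagonal-zeroed and symmetrized to
     give the predicted weighted adjacency; one round of degree-normalized
     message passing on that predicted graph yields a structural embedding;
  3. self-attention over the nodes of the step (query = [z ‖ previous
     hidden ‖ structural ‖ filled ‖ mask]) followed by MLPs gives the
     refined feature prediction, filled again against the observations.

  A single-layer GRU cell ("memory") updates the hidden state from
  [z ‖ refined output ‖ mask ‖ structural embedding].

* **Bidirectional merge** — an MLP over the concatenated per-step hidden,
  structural and output representations of both directions produces the
  final imputation.

All arrays are float64 and every stochastic draw flows from an explicit
seed, so two runs with identical inputs are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, stack
from .nn import (MLP, Adam, GRUCell, Linear, Module, MultiHeadSelfAttention,
                 StackedGRU)

__all__ = ["ModelConfig", "LatentState", "DirectionVAE", "BiVAEImputer",
           "time_encoding", "apply_filler", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_FORMAT = "ntsvae-checkpoint-v1"


@dataclass
class ModelConfig:
    hidden_dim: int = 64
    latent_dim: int = 32
    time_enc_pairs: int = 8
    attention_heads: int = 2
    mlp_hidden: int = 64
    restart_prob: float = 0.15
    n_anchors: int | None = None     # None -> ceil(log2 N)^2, capped at N
    time_scale: float = 100.0        # frequency init spans [1/time_scale, 1]
    seed: int = 0
    separate_directions: bool = True

    def __post_init__(self):
        for name in ("hidden_dim", "latent_dim", "time_enc_pairs",
                     "attention_heads", "mlp_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class LatentState:
    mean: Tensor
    log_variance: Tensor
    sample: Tensor


def time_encoding(t, freqs: Tensor) -> Tensor:
    """Unit-norm Bochner features (1/sqrt(k)) [cos w1 t, sin w1 t, ...].

    Invariant to time rescaling: encoding of a*t under frequencies w equals
    the encoding of t under frequencies a*w.  ``t`` may be a scalar (output
    shape (2k,)) or an array of timestamps (one extra leading axis).
    """
    k = freqs.shape[0]
    t_arr = np.asarray(t, dtype=np.float64)
    if t_arr.ndim == 0:
        phase = freqs * float(t_arr)
    else:
        phase = Tensor(t_arr[..., None]) * freqs
    enc = stack([phase.cos(), phase.sin()], axis=-1)
    enc = enc.reshape(enc.shape[:-2] + (2 * k,))
    return enc * (1.0 / np.sqrt(k))


def apply_filler(x_obs: Tensor | np.ndarray, mask: Tensor | np.ndarray,
                 fill: Tensor | np.ndarray):
    """mask ⊙ x_obs + (1-mask) ⊙ fill — keeps observed entries exactly."""
    if isinstance(x_obs, Tensor) or isinstance(fill, Tensor) or isinstance(mask, Tensor):
        x_obs = Tensor._lift(x_obs)
        mask = Tensor._lift(mask)
        fill = Tensor._lift(fill)
        if x_obs.shape != mask.shape or fill.shape != mask.shape:
            raise ValueError("filler operands must share one shape")
        return mask * x_obs + (1.0 - mask) * fill
    x_obs, mask, fill = (np.asarray(a, float) for a in (x_obs, mask, fill))
    if x_obs.shape != mask.shape or fill.shape != mask.shape:
        raise ValueError("filler operands must share one shape")
    return mask * x_obs + (1.0 - mask) * fill


def _init_freqs(k: int, time_scale: float) -> np.ndarray:
    cycles = np.logspace(np.log10(1.0 / max(time_scale, 2.0)), 0.0, k)
    return 2.0 * np.pi * cycles


class DirectionVAE(Module):
    """One direction of the bidirectional model (encoder + 3-stage decoder)."""

    def __init__(self, n_nodes: int, n_features: int, n_anchors: int,
                 cfg: ModelConfig, rng: np.random.Generator):
        d_h, d_z, k = cfg.hidden_dim, cfg.latent_dim, cfg.time_enc_pairs
        D, L = n_features, n_anchors
        enc_in = 2 * D + L
        self.encoder = StackedGRU(enc_in, d_h, 2, rng)
        self.head_mean = Linear(d_h, d_z, rng)
        self.head_logvar = Linear(d_h, d_z, rng)
        self.stage1 = Linear(d_h, D, rng)
        self.node_embed = Linear(2 * D + L + d_h, d_h, rng)
        self.link_mlp = MLP(2 * d_h + 2 * k, cfg.mlp_hidden, d_h, rng)
        self.prop_msg = Linear(d_h, d_h, rng)
        self.prop_self = Linear(d_h, d_h, rng)
        self.attn = MultiHeadSelfAttention(d_z + 2 * d_h + 2 * D,
                                           d_h, cfg.attention_heads, rng)
        self.attn_mlp = MLP(d_h, cfg.mlp_hidden, d_h, rng)
        self.stage3_mlp = MLP(3 * d_h, cfg.mlp_hidden, D, rng)
        self.memory = GRUCell(d_z + 2 * D + d_h, d_h, rng)
        self.time_freqs = Tensor(_init_freqs(k, cfg.time_scale),
                                 requires_grad=True)
        # initial decoder hidden state, N(0, 1/d_h); non-trainable buffer
        self.h0 = Tensor(rng.normal(0.0, np.sqrt(1.0 / d_h), (n_nodes, d_h)))
        self.n_nodes = n_nodes
        self.n_features = n_features
        self.n_anchors = n_anchors
        self.cfg = cfg

    # -- encoder ---------------------------------------------------------
    def encode(self, xs: np.ndarray, ms: np.ndarray, rs: np.ndarray,
               rng: np.random.Generator | None) -> LatentState:
        """xs, ms: (B, T, N, D); rs: (B, T, N, L).  rng None => z = mean."""
        if np.any(~np.isfinite(xs) & (ms == 1)):
            raise ValueError("non-finite feature values at observed entries")
        xs = np.nan_to_num(xs, nan=0.0) * ms  # missing entries enter as 0
        B, T = xs.shape[0], xs.shape[1]
        states = self.encoder.init_state((B, self.n_nodes))
        for t in range(T):
            step_in = Tensor(np.concatenate([xs[:, t], ms[:, t], rs[:, t]],
                                            axis=-1))
            states = self.encoder.step(step_in, states)
        h_final = states[-1]
        mean = self.head_mean(h_final)
        logvar = self.head_logvar(h_final)
        if rng is None:
            sample = mean
        else:
            eta = rng.standard_normal(mean.shape)
            sample = mean + (logvar * 0.5).exp() * Tensor(eta)
        return LatentState(mean, logvar, sample)

    # -- decoder stages --------------------------------------------------
    def predict_links(self, u: Tensor, h_prev: Tensor, tcode: Tensor) -> Tensor:
        """Score all node pairs from per-node link embeddings.

        Output is nonnegative (softplus), has zero diagonal and is
        symmetric, matching the weighted undirected adjacency semantics.
        """
        lead = u.shape[:-1]
        pad = len(lead) - (tcode.ndim - 1) - 1
        tc = tcode.reshape(tcode.shape[:-1] + (1,) * (pad + 1) + tcode.shape[-1:])
        tc = tc * Tensor(np.ones(lead + (1,)))
        emb = self.link_mlp(concat([u, h_prev, tc], axis=-1))
        scores = (emb @ emb.swap_last()) * (1.0 / np.sqrt(emb.shape[-1]))
        a = scores.softplus()
        n = self.n_nodes
        off_diag = Tensor(1.0 - np.eye(n))
        a = a * off_diag
        return (a + a.swap_last()) * 0.5

    def propagate_graph(self, u: Tensor, a_out: Tensor) -> Tensor:
        """One round of degree-normalized message passing on the predicted graph."""
        deg = a_out.sum(axis=-1, keepdims=True).clip_min(1.0)
        msg = (a_out @ u) / deg
        return (self.prop_msg(msg) + self.prop_self(u)).relu()

    def decode_step(self, x_t: np.ndarray, m_t: np.ndarray, r_t: np.ndarray,
                    z: Tensor, h_prev: Tensor, t: float) -> dict:
        """One decoder step; returns every intermediate product."""
        m = Tensor(m_t)
        x = Tensor(np.nan_to_num(x_t, nan=0.0) * m_t)
        r = Tensor(r_t)

        y1 = self.stage1(h_prev)
        o = apply_filler(x, m, y1)

        u = self.node_embed(concat([o, m, r, h_prev], axis=-1))
        tcode = time_encoding(t, self.time_freqs)
        a_out = self.predict_links(u, h_prev, tcode)
        h_graph = self.propagate_graph(u, a_out)

        attn_in = concat([z, h_prev, h_graph, o, m], axis=-1)
        h_out = self.attn_mlp(self.attn(attn_in))
        y2 = self.stage3_mlp(concat([h_out, h_prev, h_graph], axis=-1))
        x_out = apply_filler(x, m, y2)

        h = self.memory(concat([z, x_out, m, h_graph], axis=-1), h_prev)
        state = {"y1": y1, "o": o, "u": u, "a_out": a_out, "h_graph": h_graph,
                 "h_out": h_out, "y2": y2, "x_out": x_out, "h": h}
        for name, tensor in state.items():
            if not np.all(np.isfinite(tensor.data)):
                raise FloatingPointError(f"non-finite values in decoder '{name}'")
        return state

    def run_window(self, xs: np.ndarray, ms: np.ndarray, rs: np.ndarray,
                   timestamps: np.ndarray, direction: str = "forward",
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[dict], LatentState]:
        """Encode then unroll the decoder over a window.

        ``backward`` processes the time-reversed window; the returned states
        are in *processing* order (reverse them to align with forward time).
        """
        if direction not in ("forward", "backward"):
            raise ValueError(f"direction must be forward/backward, got {direction!r}")
        timestamps = np.asarray(timestamps, dtype=np.float64)
        if direction == "backward":
            xs, ms, rs = xs[:, ::-1], ms[:, ::-1], rs[:, ::-1]
            timestamps = timestamps[..., ::-1]
        latent = self.encode(xs, ms, rs, rng)
        B, T = xs.shape[0], xs.shape[1]
        h = Tensor(np.broadcast_to(self.h0.data, (B,) + self.h0.shape).copy())
        states = []
        for t in range(T):
            state = self.decode_step(xs[:, t], ms[:, t], rs[:, t],
                                     latent.sample, h, timestamps[..., t])
            states.append(state)
            h = state["h"]
        return states, latent


class BiVAEImputer(Module):
    """Forward + backward VAEs with an MLP merge head."""

    def __init__(self, n_nodes: int, n_features: int, n_anchors: int,
                 cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.forward = DirectionVAE(n_nodes, n_features, n_anchors, cfg, rng)
        if cfg.separate_directions:
            self.backward = DirectionVAE(n_nodes, n_features, n_anchors, cfg, rng)
        else:
            self.backward = self.forward
        d_h = cfg.hidden_dim
        self.merge_mlp = MLP(6 * d_h, cfg.mlp_hidden, n_features, rng)
        self.cfg = cfg
        self.n_nodes = n_nodes
        self.n_features = n_features
        self.n_anchors = n_anchors

    def merge_bidirectional(self, fstates: list[dict],
                            bstates: list[dict]) -> list[Tensor]:
        """Per-step merge; ``bstates`` must already be re-aligned to forward time."""
        if len(fstates) != len(bstates):
            raise ValueError("direction outputs cover different window lengths")
        merged = []
        for f, b in zip(fstates, bstates):
            feats = concat([f["h_out"], b["h_out"], f["h_graph"], b["h_graph"],
                            f["h"], b["h"]], axis=-1)
            merged.append(self.merge_mlp(feats))
        return merged

    def run_bidirectional(self, xs: np.ndarray, ms: np.ndarray, rs: np.ndarray,
                          timestamps: np.ndarray,
                          rng_f: np.random.Generator | None = None,
                          rng_b: np.random.Generator | None = None) -> dict:
        fstates, lat_f = self.forward.run_window(xs, ms, rs, timestamps,
                                                 "forward", rng_f)
        bstates, lat_b = self.backward.run_window(xs, ms, rs, timestamps,
                                                  "backward", rng_b)
        bstates = bstates[::-1]  # re-align to forward time
        merged = self.merge_bidirectional(fstates, bstates)
        return {"forward": fstates, "backward": bstates, "merged": merged,
                "latent_f": lat_f, "latent_b": lat_b}

    # -- persistence -----------------------------------------------------
    def buffers(self) -> list[Tensor]:
        bufs = [self.forward.h0]
        if self.backward is not self.forward:
            bufs.append(self.backward.h0)
        return bufs


def save_checkpoint(model: BiVAEImputer, path: str | Path,
                    extra: dict | None = None) -> None:
    path = Path(path)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    for i, b in enumerate(model.buffers()):
        arrays[f"buffer_{i}"] = b.data
    meta = {
        "format": CHECKPOINT_FORMAT,
        "config": asdict(model.cfg),
        "n_nodes": model.n_nodes,
        "n_features": model.n_features,
        "n_anchors": model.n_anchors,
        "extra": extra or {},
    }
    with open(path, "wb") as fh:  # keep the exact path (savez appends .npz)
        np.savez(fh, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[BiVAEImputer, dict]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognized checkpoint format: {meta.get('format')}")
        cfg = ModelConfig(**meta["config"])
        model = BiVAEImputer(meta["n_nodes"], meta["n_features"],
                             meta["n_anchors"], cfg)
        params = model.parameters()
        model.load_state_arrays([data[f"param_{i}"] for i in range(len(params))])
        for i, b in enumerate(model.buffers()):
            b.data = data[f"buffer_{i}"]
    return model, meta["extra"]
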