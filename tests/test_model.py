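"""VAE architecture contracts: determinism, conservation, equivariance."""

import numpy as np
import pytest

from ntsvae.autodiff import Tensor
from ntsvae.model import (BiVAEImputer, DirectionVAE, ModelConfig,
                          apply_filler, time_encoding)

TINY = ModelConfig(hidden_dim=8, latent_dim=4, time_enc_pairs=2,
                   attention_heads=2, mlp_hidden=8, seed=5, time_scale=10)


def _direction(n=4, d=1, l=2, cfg=TINY, seed=None):
    c = ModelConfig(**{**cfg.__dict__, **({"seed": seed} if seed is not None else {})})
    rng = np.random.default_rng(c.seed)
    return DirectionVAE(n, d, l, c, rng)


def _window_data(rng, b=2, t=3, n=4, d=1, l=2, missing=0.3):
    xs = rng.standard_normal((b, t, n, d))
    ms = (rng.uniform(size=(b, t, n, d)) > missing).astype(float)
    rs = rng.dirichlet(np.ones(n), size=(b, t, l)).transpose(0, 1, 3, 2)
    ts = np.broadcast_to(np.arange(t, dtype=float), (b, t)).copy()
    return xs, ms, rs, ts


# ---------------------------------------------------------------- time encoding

def test_time_encoding_zero_frequencies():
    enc = time_encoding(3.7, Tensor(np.zeros(3))).data
    assert np.allclose(enc, np.tile([1, 0], 3) / np.sqrt(3))
    assert np.isclose(np.linalg.norm(enc), 1.0)


def test_time_encoding_known_value():
    enc = time_encoding(np.pi, Tensor(np.array([1.0, 2.0]))).data
    assert np.allclose(enc, np.array([-1, 0, 1, 0]) / np.sqrt(2), atol=1e-12)


def test_time_encoding_unit_norm_and_rescaling_identity():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        k = int(rng.integers(1, 9))
        w = rng.uniform(0.01, 5.0, size=k)
        t = float(rng.uniform(-20, 20))
        alpha = float(rng.uniform(0.1, 10.0))
        e1 = time_encoding(alpha * t, Tensor(w)).data
        e2 = time_encoding(t, Tensor(alpha * w)).data
        assert np.max(np.abs(e1 - e2)) < 1e-12
        assert abs(np.linalg.norm(e1) - 1.0) < 1e-12


# ---------------------------------------------------------------------- filler

@pytest.mark.parametrize("mask,expected", [
    (np.ones((1, 2)), [[2.0, 5.0]]),
    (np.zeros((1, 2)), [[9.0, 7.0]]),
    (np.array([[1.0, 0.0]]), [[2.0, 7.0]]),
])
def test_filler_blends_observed_and_predicted(mask, expected):
    x = np.array([[2.0, 5.0]])
    fill = np.array([[9.0, 7.0]])
    assert np.array_equal(apply_filler(x, mask, fill), expected)


def test_filler_shape_mismatch():
    with pytest.raises(ValueError):
        apply_filler(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 3)))


# --------------------------------------------------------------------- encoder

def test_encoder_deterministic_under_seed(rng):
    d = _direction()
    xs, ms, rs, _ = _window_data(np.random.default_rng(4))
    l1 = d.encode(xs, ms, rs, np.random.default_rng(9))
    l2 = d.encode(xs, ms, rs, np.random.default_rng(9))
    assert np.array_equal(l1.sample.data, l2.sample.data)
    assert np.array_equal(l1.mean.data, l2.mean.data)


def test_zeroed_heads_sit_at_prior():
    d = _direction()
    d.head_mean.weight.data[:] = 0
    d.head_mean.bias.data[:] = 0
    d.head_logvar.weight.data[:] = 0
    d.head_logvar.bias.data[:] = 0
    xs, ms, rs, _ = _window_data(np.random.default_rng(4))
    lat = d.encode(xs, ms, rs, None)
    assert np.array_equal(lat.mean.data, np.zeros_like(lat.mean.data))
    assert np.array_equal(lat.log_variance.data, np.zeros_like(lat.mean.data))
    kl = -0.5 * np.mean(1 + lat.log_variance.data - lat.mean.data**2
                        - np.exp(lat.log_variance.data))
    assert kl == 0.0


def test_encoder_finite_and_kl_nonnegative(rng):
    d = _direction()
    xs, ms, rs, _ = _window_data(np.random.default_rng(0))
    lat = d.encode(xs, ms, rs, np.random.default_rng(0))
    assert np.all(np.isfinite(lat.mean.data))
    assert np.all(np.isfinite(lat.log_variance.data))
    kl = -0.5 * np.mean(1 + lat.log_variance.data - lat.mean.data**2
                        - np.exp(lat.log_variance.data))
    assert kl >= 0.0


def test_encoder_rejects_nonfinite_observed():
    d = _direction()
    xs, ms, rs, _ = _window_data(np.random.default_rng(4))
    xs[0, 0, 0, 0] = np.inf
    ms[0, 0, 0, 0] = 1.0
    with pytest.raises(ValueError):
        d.encode(xs, ms, rs, None)


# -------------------------------------------------------------- link prediction

def test_zero_parameter_link_head_gives_constant_softplus():
    d = _direction()
    for layer in (d.link_mlp.fc1, d.link_mlp.fc2):
        layer.weight.data[:] = 0
        layer.bias.data[:] = 0
    u = Tensor(np.random.default_rng(0).standard_normal((4, 8)))
    h = Tensor(np.zeros((4, 8)))
    a = d.predict_links(u, h, time_encoding(0.0, d.time_freqs)).data
    assert np.allclose(np.diag(a), 0.0)
    off = a[~np.eye(4, dtype=bool)]
    assert np.allclose(off, off[0])  # constant softplus(0) off-diagonal


def test_predicted_adjacency_symmetric_nonnegative_zero_diagonal(rng):
    d = _direction()
    u = Tensor(rng.standard_normal((3, 4, 8)))
    h = Tensor(rng.standard_normal((3, 4, 8)))
    a = d.predict_links(u, h, time_encoding(1.5, d.time_freqs)).data
    assert np.allclose(a, np.swapaxes(a, -1, -2))
    assert np.all(a >= 0)
    assert np.allclose(a[:, np.arange(4), np.arange(4)], 0.0)


def test_link_prediction_permutation_equivariant(rng):
    d = _direction()
    u_data = rng.standard_normal((4, 8))
    h_data = rng.standard_normal((4, 8))
    tc = time_encoding(2.0, d.time_freqs)
    a = d.predict_links(Tensor(u_data), Tensor(h_data), tc).data
    perm = np.random.default_rng(1).permutation(4)
    a_p = d.predict_links(Tensor(u_data[perm]), Tensor(h_data[perm]), tc).data
    assert np.allclose(a_p, a[np.ix_(perm, perm)], atol=1e-12)


# ------------------------------------------------------------- message passing

def test_empty_graph_leaves_only_self_term(rng):
    d = _direction()
    u_data = rng.standard_normal((4, 8))
    out = d.propagate_graph(Tensor(u_data), Tensor(np.zeros((4, 4)))).data
    expected = np.maximum(
        u_data @ d.prop_msg.weight.data * 0  # no neighbour term
        + u_data @ d.prop_self.weight.data + d.prop_self.bias.data
        + d.prop_msg.bias.data, 0.0)
    assert np.allclose(out, expected)


def test_propagation_permutation_equivariant(rng):
    d = _direction()
    u_data = rng.standard_normal((4, 8))
    a_data = np.abs(rng.standard_normal((4, 4)))
    np.fill_diagonal(a_data, 0.0)
    out = d.propagate_graph(Tensor(u_data), Tensor(a_data)).data
    perm = np.random.default_rng(2).permutation(4)
    out_p = d.propagate_graph(Tensor(u_data[perm]),
                              Tensor(a_data[np.ix_(perm, perm)])).data
    assert np.allclose(out_p, out[perm], atol=1e-12)


def test_automorphic_nodes_get_identical_embeddings(rng):
    # 4-cycle with the swap (0<->2) automorphism; give 0 and 2 identical rows
    d = _direction()
    a = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]],
                 dtype=float)
    u_data = rng.standard_normal((4, 8))
    u_data[2] = u_data[0]
    u_data[3] = u_data[1]
    out = d.propagate_graph(Tensor(u_data), Tensor(a)).data
    assert np.max(np.abs(out[0] - out[2])) < 1e-9
    assert np.max(np.abs(out[1] - out[3])) < 1e-9


# ----------------------------------------------------------------- decode step

def test_decoder_conserves_observed_entries(rng):
    d = _direction()
    xs, ms, rs, _ = _window_data(np.random.default_rng(8))
    z = Tensor(rng.standard_normal((2, 4, 4)))
    h = Tensor(rng.standard_normal((2, 4, 8)))
    state = d.decode_step(xs[:, 0], ms[:, 0], rs[:, 0], z, h, 0.0)
    sel = ms[:, 0] == 1
    assert np.array_equal(state["o"].data[sel], xs[:, 0][sel])
    assert np.array_equal(state["x_out"].data[sel], xs[:, 0][sel])


def test_decode_step_deterministic_and_finite(rng):
    d = _direction()
    xs, ms, rs, _ = _window_data(np.random.default_rng(8))
    z = Tensor(rng.standard_normal((2, 4, 4)))
    h = Tensor(rng.standard_normal((2, 4, 8)))
    s1 = d.decode_step(xs[:, 0], ms[:, 0], rs[:, 0], z, h, 0.5)
    s2 = d.decode_step(xs[:, 0], ms[:, 0], rs[:, 0], z, h, 0.5)
    for key in s1:
        assert np.array_equal(s1[key].data, s2[key].data)
        assert np.all(np.isfinite(s1[key].data))
    a = s1["a_out"].data
    assert np.allclose(a[:, np.arange(4), np.arange(4)], 0.0)


def test_decode_step_permutation_consistency(rng):
    d = _direction()
    xs, ms, rs, _ = _window_data(np.random.default_rng(8), b=1)
    z_data = rng.standard_normal((1, 4, 4))
    h_data = rng.standard_normal((1, 4, 8))
    s = d.decode_step(xs[:, 0], ms[:, 0], rs[:, 0],
                      Tensor(z_data), Tensor(h_data), 1.0)
    perm = np.array([2, 0, 3, 1])
    sp = d.decode_step(xs[:, 0][:, perm], ms[:, 0][:, perm], rs[:, 0][:, perm],
                       Tensor(z_data[:, perm]), Tensor(h_data[:, perm]), 1.0)
    assert np.allclose(sp["x_out"].data, s["x_out"].data[:, perm], atol=1e-9)
    assert np.allclose(sp["o"].data, s["o"].data[:, perm], atol=1e-9)
    assert np.allclose(sp["a_out"].data,
                       s["a_out"].data[:, perm][:, :, perm], atol=1e-9)


# ------------------------------------------------------------------ run window

def test_single_step_window():
    d = _direction()
    xs, ms, rs, ts = _window_data(np.random.default_rng(1), t=1)
    states, latent = d.run_window(xs, ms, rs, ts, "forward",
                                  np.random.default_rng(0))
    assert len(states) == 1


def test_all_masked_window_still_runs():
    d = _direction()
    xs, ms, rs, ts = _window_data(np.random.default_rng(1))
    ms[:] = 0.0
    xs[:] = np.nan
    states, _ = d.run_window(xs, ms, rs, ts, "forward", np.random.default_rng(0))
    for s in states:
        assert np.all(np.isfinite(s["x_out"].data))


def test_backward_on_palindrome_mirrors_forward():
    """With copied parameters, the backward pass over a time-symmetric window
    reproduces the forward pass in reverse."""
    fwd = _direction(seed=5)
    bwd = _direction(seed=6)
    bwd.load_state_arrays(fwd.state_arrays())
    bwd.h0.data = fwd.h0.data.copy()
    rng = np.random.default_rng(2)
    half_x = rng.standard_normal((1, 3, 4, 1))
    half_m = (rng.uniform(size=(1, 3, 4, 1)) > 0.3).astype(float)
    half_r = rng.dirichlet(np.ones(4), size=(1, 3, 2)).transpose(0, 1, 3, 2)
    xs = np.concatenate([half_x, half_x[:, ::-1]], axis=1)
    ms = np.concatenate([half_m, half_m[:, ::-1]], axis=1)
    rs = np.concatenate([half_r, half_r[:, ::-1]], axis=1)
    ts = np.zeros((1, 6))  # constant clock keeps the window fully symmetric
    f_states, _ = fwd.run_window(xs, ms, rs, ts, "forward",
                                 np.random.default_rng(0))
    b_states, _ = bwd.run_window(xs, ms, rs, ts, "backward",
                                 np.random.default_rng(0))
    for fs, bs in zip(f_states, b_states):
        assert np.max(np.abs(fs["x_out"].data - bs["x_out"].data)) < 1e-9
        assert np.max(np.abs(fs["a_out"].data - bs["a_out"].data)) < 1e-9


# ----------------------------------------------------------------------- merge

def test_merge_zero_final_layer_returns_bias(rng):
    model = BiVAEImputer(4, 1, 2, TINY)
    model.merge_mlp.fc2.weight.data[:] = 0
    model.merge_mlp.fc2.bias.data[:] = 0.75
    xs, ms, rs, ts = _window_data(np.random.default_rng(3))
    out = model.run_bidirectional(xs, ms, rs, ts)
    for y in out["merged"]:
        assert np.allclose(y.data, 0.75)
        assert y.shape == (2, 4, 1)


def test_merge_length_mismatch_raises():
    model = BiVAEImputer(4, 1, 2, TINY)
    xs, ms, rs, ts = _window_data(np.random.default_rng(3))
    out = model.run_bidirectional(xs, ms, rs, ts)
    with pytest.raises(ValueError):
        model.merge_bidirectional(out["forward"], out["backward"][:-1])


def test_bidirectional_deterministic_under_seed():
    model = BiVAEImputer(4, 1, 2, TINY)
    xs, ms, rs, ts = _window_data(np.random.default_rng(3))
    o1 = model.run_bidirectional(xs, ms, rs, ts,
                                 np.random.default_rng(1), np.random.default_rng(2))
    o2 = model.run_bidirectional(xs, ms, rs, ts,
                                 np.random.default_rng(1), np.random.default_rng(2))
    for y1, y2 in zip(o1["merged"], o2["merged"]):
        assert np.array_equal(y1.data, y2.data)


def test_smoke_random_configs_stay_finite():
    rng = np.random.default_rng(0)
    for trial in range(12):
        cfg = ModelConfig(
            hidden_dim=int(rng.integers(4, 12)),
            latent_dim=int(rng.integers(2, 8)),
            time_enc_pairs=int(rng.integers(1, 4)),
            attention_heads=2, mlp_hidden=int(rng.integers(4, 12)),
            seed=trial, time_scale=8)
        cfg.hidden_dim += cfg.hidden_dim % 2  # divisible by heads
        model = BiVAEImputer(3, 2, 2, cfg)
        xs, ms, rs, ts = _window_data(rng, b=1, t=2, n=3, d=2)
        out = model.run_bidirectional(xs, ms, rs, ts, np.random.default_rng(trial),
                                      np.random.default_rng(trial))
        for y in out["merged"]:
            assert np.all(np.isfinite(y.data))
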