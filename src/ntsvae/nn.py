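"""Neural-network building blocks on top of the autodiff engine.

Layers hold their parameters as ``Tensor`` leaves with ``requires_grad=True``
and expose ``parameters()`` for the optimizer.  All initialisation is driven
by an explicit ``numpy.random.Generator`` so that model construction is fully
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["Module", "Linear", "MLP", "GRUCell", "StackedGRU",
           "MultiHeadSelfAttention", "Adam"]


class Module:
    """Base class: recursively collects parameters from attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(
                    f"shape mismatch in checkpoint: {a.shape} vs {p.data.shape}"
                )
            p.data = np.asarray(a, dtype=np.float64)


def _collect(value):
    if isinstance(value, Tensor):
        if value.requires_grad:
            yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Two-layer perceptron with ReLU hidden activation."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int,
                 rng: np.random.Generator):
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class GRUCell(Module):
    """Standard gated recurrent cell (reset/update gates, candidate state).

    Gate weights are kept as separate matrices (rather than one fused 3d_h
    block) so every product hits the fast 2-D-weight matmul path.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.w_ir = Tensor(_glorot(rng, in_dim, hidden), requires_grad=True)
        self.w_iu = Tensor(_glorot(rng, in_dim, hidden), requires_grad=True)
        self.w_in = Tensor(_glorot(rng, in_dim, hidden), requires_grad=True)
        self.w_hr = Tensor(_glorot(rng, hidden, hidden), requires_grad=True)
        self.w_hu = Tensor(_glorot(rng, hidden, hidden), requires_grad=True)
        self.w_hn = Tensor(_glorot(rng, hidden, hidden), requires_grad=True)
        self.b_r = Tensor(np.zeros(hidden), requires_grad=True)
        self.b_u = Tensor(np.zeros(hidden), requires_grad=True)
        self.b_n = Tensor(np.zeros(hidden), requires_grad=True)
        self.b_hn = Tensor(np.zeros(hidden), requires_grad=True)
        self.hidden = hidden

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        r = (x @ self.w_ir + h @ self.w_hr + self.b_r).sigmoid()
        u = (x @ self.w_iu + h @ self.w_hu + self.b_u).sigmoid()
        n = (x @ self.w_in + r * (h @ self.w_hn + self.b_hn) + self.b_n).tanh()
        return (1.0 - u) * n + u * h


class StackedGRU(Module):
    """Multi-layer GRU unrolled step by step by the caller."""

    def __init__(self, in_dim: int, hidden: int, layers: int,
                 rng: np.random.Generator):
        self.cells = [
            GRUCell(in_dim if i == 0 else hidden, hidden, rng)
            for i in range(layers)
        ]
        self.hidden = hidden
        self.layers = layers

    def init_state(self, batch_shape: tuple[int, ...]) -> list[Tensor]:
        return [Tensor(np.zeros(batch_shape + (self.hidden,)))
                for _ in range(self.layers)]

    def step(self, x: Tensor, states: list[Tensor]) -> list[Tensor]:
        new_states = []
        inp = x
        for cell, h in zip(self.cells, states):
            inp = cell(inp, h)
            new_states.append(inp)
        return new_states


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over the second-to-last axis.

    Input shape (..., N, in_dim); attention mixes the N positions (here:
    the nodes within one time step).
    """

    def __init__(self, in_dim: int, model_dim: int, heads: int,
                 rng: np.random.Generator):
        if model_dim % heads != 0:
            raise ValueError("model_dim must be divisible by heads")
        self.heads = heads
        self.head_dim = model_dim // heads
        self.model_dim = model_dim
        self.wq = Linear(in_dim, model_dim, rng)
        self.wk = Linear(in_dim, model_dim, rng)
        self.wv = Linear(in_dim, model_dim, rng)
        self.wo = Linear(model_dim, model_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        lead = x.shape[:-2]
        n = x.shape[-2]
        h, dk = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            # (..., N, h*dk) -> (..., h, N, dk)
            t = t.reshape(lead + (n, h, dk))
            axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
            return t.transpose(axes)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swap_last()) * (1.0 / np.sqrt(dk))
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (..., h, N, dk)
        axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
        out = out.transpose(axes).reshape(lead + (n, h * dk))
        return self.wo(out)


class Adam:
    """Adam optimizer with bias correction (no weight decay)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g**2
            m_hat = self.m[i] / b1t
            v_hat = self.v[i] / b2t
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
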