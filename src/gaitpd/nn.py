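"""Neural-network building blocks on top of :mod:`gaitpd.autodiff`.

Layers hold their parameters as ``Tensor``s with ``requires_grad=True`` and
expose them through :meth:`Module.parameters` /
:meth:`Module.weight_matrices` (the latter feeds the L1/L2 regularizers,
which by convention exclude biases and normalization gains).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, layer_norm

DTYPE = np.float32


class Module:
    """Minimal container: submodules and parameters discovered by attribute."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def weight_matrices(self) -> list[Tensor]:
        """Parameters subject to L1/L2 regularization (ndim >= 2)."""
        return [p for p in self.parameters() if p.data.ndim >= 2]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.W = Tensor(
            rng.normal(0.0, scale, size=(d_in, d_out)).astype(DTYPE),
            requires_grad=True,
        )
        self.b = (
            Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True) if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.b = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.g, self.b, self.eps)


class Dropout(Module):
    """Inverted dropout; identity when `rng` is None (inference)."""

    def __init__(self, p: float):
        self.p = float(p)

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        if rng is None or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * mask


class MultiheadAttention(Module):
    """Scaled dot-product attention with learned Q/K/V/output projections.

    Self-attention passes the same sequence as query and key/value; the
    cross-view exchange passes the other stream as key/value.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"embed dim {dim} not divisible by {heads} heads")
        self.dim, self.heads, self.head_dim = dim, heads, dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def _split(self, x: Tensor, b: int, t: int) -> Tensor:
        return x.reshape(b, t, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x_q: Tensor, x_kv: Tensor) -> Tensor:
        b, t, _ = x_q.shape
        tk = x_kv.shape[1]
        q = self._split(self.wq(x_q), b, t)
        k = self._split(self.wk(x_kv), b, tk)
        v = self._split(self.wv(x_kv), b, tk)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, self.dim)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).silu())
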