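"""Compact reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates vector-Jacobian products into ``.grad``. The op set is
exactly what the gait-fusion network needs: broadcast arithmetic, (batched)
matmul, reductions, shape moves, the usual pointwise nonlinearities, and a
cumulative sum (used by the chunked state-space scan).

All gradients are plain ``ndarray``s of the same dtype as the data; the
engine is dtype-agnostic (the network runs in float32, oracle checks in
float64).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "as_tensor", "layer_norm"]


_SCALARS = (int, float, np.integer, np.floating)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims that were added
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over dims that were 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ---------------------------------------------------------------- infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray):
        # grads are never mutated in place anywhere in the engine, so the
        # incoming array can be adopted without a defensive copy
        if self.grad is None:
            self.grad = np.asarray(g)
        else:
            self.grad = self.grad + g

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None):
        """Accumulate gradients into every reachable leaf.

        The tape is released while it is consumed (intermediate grads and
        edges are dropped as soon as their VJP has run), so a graph can be
        backpropagated exactly once.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free buffers as soon as a node's VJP has run: only leaf
                # gradients are needed after backward completes
                node.grad = None
                node._backward = None
                node._prev = ()

    # ----------------------------------------------------------- arithmetic
    # Python scalars take a fast path that leans on NumPy's weak promotion,
    # so float32 graphs are not silently promoted to float64 by constants.
    def __add__(self, other):
        if isinstance(other, _SCALARS):
            c = float(other)

            def backward_s(g):
                if self.requires_grad:
                    self._accum(g)

            return Tensor._make(self.data + c, (self,), backward_s)
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        if isinstance(other, _SCALARS):
            return self + (-float(other))
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, _SCALARS):
            return (-self) + float(other)
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, _SCALARS):
            c = float(other)

            def backward_s(g):
                if self.requires_grad:
                    self._accum(g * c)

            return Tensor._make(self.data * c, (self,), backward_s)
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, _SCALARS):
            return self * (1.0 / float(other))
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # ------------------------------------------------------------ pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(g):
            if self.requires_grad:
                self._accum(g * (s + self.data * s * (1.0 - s)))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        return Tensor._make(t, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s)

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def cumsum(self, axis: int):
        out_data = np.cumsum(self.data, axis=axis)

        def backward(g):
            if self.requires_grad:
                rev = np.flip(np.cumsum(np.flip(g, axis), axis=axis), axis)
                self._accum(rev)

        return Tensor._make(out_data, (self,), backward)

    # --------------------------------------------------------------- shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        # basic slices and sorted-unique fancy indices never alias, so the
        # cheap scatter is safe; np.add.at is only needed for repeats
        repeats = isinstance(idx, np.ndarray) and np.unique(idx).size != idx.size

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if repeats:
                    np.add.at(full, idx, g)
                else:
                    full[idx] = g
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # ------------------------------------------------------------ fused ops
    # single-node softmax and layer norm keep the tape small: a composed
    # version would add ~10 batch-sized intermediates per call
    def softmax(self, axis: int = -1):
        e = np.exp(self.data - np.max(self.data, axis=axis, keepdims=True))
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = np.sum(g * out_data, axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis (single tape node)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = xc * inv
    out_data = xn * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            axes = tuple(range(g.ndim - 1))
            gamma._accum(np.sum(g * xn, axis=axes))
        if beta.requires_grad:
            axes = tuple(range(g.ndim - 1))
            beta._accum(np.sum(g, axis=axes))
        if x.requires_grad:
            dxn = g * gamma.data
            m1 = dxn.mean(axis=-1, keepdims=True)
            m2 = np.mean(dxn * xn, axis=-1, keepdims=True)
            x._accum(inv * (dxn - m1 - xn * m2))

    return Tensor._make(out_data, (x, gamma, beta), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)
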