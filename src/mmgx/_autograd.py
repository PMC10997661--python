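"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The graph-network layers in :mod:`mmgx.network` need only a small set of
dense and segment (scatter/gather) operations, so the engine is deliberately
tiny: a :class:`Tensor` wrapping a float64 ``ndarray``, a tape built through
closures, and topological-order backpropagation.  float64 everywhere keeps
CPU runs bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "segment_mean",
    "segment_softmax",
]


class Tensor:
    """An ndarray node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- infrastructure ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _unbroadcast(g, shape):
        """Sum gradient ``g`` down to ``shape`` (reverse of NumPy broadcast)."""
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for i, s in enumerate(shape):
            if s == 1 and g.shape[i] != 1:
                g = g.sum(axis=i, keepdims=True)
        return g.reshape(shape)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    # -- reductions & nonlinearities --------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def _unary(self, y, dydx):
        out = Tensor(y, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * dydx)

        out._backward = bw
        return out

    def relu(self):
        y = np.maximum(self.data, 0.0)
        return self._unary(y, (self.data > 0).astype(np.float64))

    def leaky_relu(self, alpha=0.2):
        y = np.where(self.data > 0, self.data, alpha * self.data)
        return self._unary(y, np.where(self.data > 0, 1.0, alpha))

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(y, y * (1.0 - y))

    def tanh(self):
        y = np.tanh(self.data)
        return self._unary(y, 1.0 - y * y)

    def softplus(self):
        y = np.logaddexp(0.0, self.data)
        return self._unary(y, 1.0 / (1.0 + np.exp(-self.data)))

    def log(self):
        return self._unary(np.log(self.data), 1.0 / self.data)

    def exp(self):
        y = np.exp(self.data)
        return self._unary(y, y)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out


def concat(tensors, axis=-1):
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def gather(t, idx):
    """Select rows ``t[idx]`` with scatter-add backward."""
    return t[np.asarray(idx)]


def segment_sum(t, seg_ids, num_segments):
    """Sum rows of ``t`` into ``num_segments`` buckets given per-row ids."""
    seg_ids = np.asarray(seg_ids)
    data = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(data, seg_ids, t.data)
    out = Tensor(data, _prev=(t,))

    def bw(g):
        if t.requires_grad:
            t._accum(g[seg_ids])

    out._backward = bw
    return out


def segment_mean(t, seg_ids, num_segments):
    seg_ids = np.asarray(seg_ids)
    counts = np.bincount(seg_ids, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    s = segment_sum(t, seg_ids, num_segments)
    return s * (1.0 / counts)[:, None]


def segment_softmax(t, seg_ids, num_segments):
    """Softmax of a column vector ``t`` (shape (n, 1) or (n,)) within segments."""
    seg_ids = np.asarray(seg_ids)
    x = t.data.reshape(-1)
    # max-shift per segment for numerical stability
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, seg_ids, x)
    ex = np.exp(x - seg_max[seg_ids])
    denom = np.zeros(num_segments)
    np.add.at(denom, seg_ids, ex)
    y = ex / denom[seg_ids]
    out = Tensor(y.reshape(t.data.shape), _prev=(t,))

    def bw(g):
        if t.requires_grad:
            gy = (g.reshape(-1)) * y
            dot = np.zeros(num_segments)
            np.add.at(dot, seg_ids, gy)
            t._accum((gy - y * dot[seg_ids]).reshape(t.data.shape))

    out._backward = bw
    return out
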