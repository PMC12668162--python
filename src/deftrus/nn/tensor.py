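"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` replays them in reverse topological order to
accumulate gradients.  Only the operations needed by the translation networks
and their losses are implemented (elementwise arithmetic, matmul, reductions,
shape ops, gather/concat, and the usual nonlinearities); convolution and the
other image-specific primitives live in :mod:`deftrus.nn.functional`.

Gradients follow NumPy broadcasting: a gradient flowing into a broadcast
operand is summed back down to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "concat", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = np.asarray(grad, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        out = Tensor._make(self.data ** p, (self,), None)

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * 0.5 / y)
        return out

    def abs(self):
        out = Tensor._make(np.abs(self.data), (self,), None)
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2):
        scale = np.where(self.data > 0, 1.0, slope)
        out = Tensor._make(self.data * scale, (self,), None)
        out._backward = lambda g: self._accum(g * scale)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp; gradient passes only where the value was not clipped."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor._make(self.data.reshape(shape), (self,), None)
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(axes), (self,), None)
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def index_select(self, axis: int, idx: np.ndarray):
        """Gather along ``axis`` with integer indices (differentiable)."""
        idx = np.asarray(idx)
        out = Tensor._make(np.take(self.data, idx, axis=axis), (self,), None)

        def bw(g):
            full = np.zeros_like(self.data)
            sl = [slice(None)] * self.data.ndim
            sl[axis] = idx
            np.add.at(full, tuple(sl), g)
            self._accum(full)

        out._backward = bw
        return out


def astensor(x) -> Tensor:
    """Wrap as Tensor; float32 arrays stay float32 (the training dtype),
    everything else is promoted to float64."""
    if isinstance(x, Tensor):
        return x
    a = np.asarray(x)
    if a.dtype == np.float32:
        return Tensor(a)
    return Tensor(a.astype(np.float64))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), None)
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
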