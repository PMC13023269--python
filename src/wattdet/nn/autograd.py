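"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: every :class:`Tensor` wraps a ``float32``
ndarray and records a closure that propagates gradients to its parents.
Only the operations needed by the detection stack are implemented
(convolution, batch normalization, pooling, elementwise math, matmul,
softmax, reductions, reshaping).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "cat", "stack"]

_grad_enabled = [True]


@contextlib.contextmanager
def no_grad():
    _grad_enabled.append(False)
    try:
        yield
    finally:
        _grad_enabled.pop()


def is_grad_enabled() -> bool:
    return _grad_enabled[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
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
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self._backward: Callable[[], None] | None = None
        self._prev: tuple = ()

    # ------------------------------------------------------------- plumbing
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [self]
        while stack:  # iterative DFS: graphs can be deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._prev if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # ------------------------------------------------------------ factories
    @staticmethod
    def _make(data, parents: Iterable["Tensor"], backward) -> "Tensor":
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data)
        out.requires_grad = req
        if req:
            out._prev = parents
            out._backward = backward(out)
        return out

    # ---------------------------------------------------------- elementwise
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad, other.shape))
            return fn

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(-out.grad)
            return fn

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad * other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad * self.data, other.shape))
            return fn

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad / other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(
                        -out.grad * self.data / (other.data ** 2), other.shape))
            return fn

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(out.grad * p * self.data ** (p - 1))
            return fn

        return Tensor._make(self.data ** p, (self,), bw)

    def exp(self):
        data = np.exp(self.data)

        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(out.grad * out.data)
            return fn

        return Tensor._make(data, (self,), bw)

    def log(self):
        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(out.grad / self.data)
            return fn

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(out.grad * np.sign(self.data))
            return fn

        return Tensor._make(np.abs(self.data), (self,), bw)

    def clamp(self, lo=None, hi=None):
        data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask = mask * (self.data >= lo)
        if hi is not None:
            mask = mask * (self.data <= hi)

        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(out.grad * mask)
            return fn

        return Tensor._make(data, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(out.grad * out.data * (1.0 - out.data))
            return fn

        return Tensor._make(s, (self,), bw)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(out.grad * (s + self.data * s * (1.0 - s)))
            return fn

        return Tensor._make(self.data * s, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(out.grad * mask)
            return fn

        return Tensor._make(self.data * mask, (self,), bw)

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(out):
            def fn():
                if not self.requires_grad:
                    return
                g = out.grad
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, tuple(a % self.ndim for a in axes))
                self._accum(np.broadcast_to(g, self.shape))
            return fn

        return Tensor._make(data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        data = self.data.max(axis=axis, keepdims=keepdims)

        def bw(out):
            def fn():
                if not self.requires_grad:
                    return
                g = out.grad
                d = out.data
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, tuple(a % self.ndim for a in axes))
                    d = np.expand_dims(d, tuple(a % self.ndim for a in axes))
                mask = (self.data == d)
                # split gradient between ties to keep it a valid subgradient
                cnt = mask.sum(axis=axis, keepdims=True) if axis is not None \
                    else mask.sum()
                self._accum(mask * g / cnt)
            return fn

        return Tensor._make(data, (self,), bw)

    # --------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(out.grad.reshape(self.shape))
            return fn

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(out):
            def fn():
                if self.requires_grad:
                    self._accum(out.grad.transpose(inv))
            return fn

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(out):
            def fn():
                if self.requires_grad:
                    g = np.zeros_like(self.data)
                    np.add.at(g, idx, out.grad)
                    self._accum(g)
            return fn

        return Tensor._make(self.data[idx], (self,), bw)

    def pad2d(self, pad: int, mode: str = "constant"):
        """Pad the two trailing spatial axes by ``pad`` on every side."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        data = np.pad(self.data, width, mode=mode)
        sl = (Ellipsis, slice(pad, data.shape[-2] - pad),
              slice(pad, data.shape[-1] - pad))

        def bw(out):
            def fn():
                if not self.requires_grad:
                    return
                if mode == "constant":
                    self._accum(out.grad[sl])
                else:  # reflect: fold mirrored border gradients back inside
                    self._accum(_fold_reflect(out.grad, self.shape, pad))
            return fn

        return Tensor._make(data, (self,), bw)

    def matmul(self, other: "Tensor"):
        def bw(out):
            def fn():
                g = out.grad
                if self.requires_grad:
                    self._accum(_unbroadcast(
                        np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(
                        np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape))
            return fn

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    __matmul__ = matmul

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(out):
            def fn():
                if self.requires_grad:
                    g = out.grad
                    dot = (g * out.data).sum(axis=axis, keepdims=True)
                    self._accum(out.data * (g - dot))
            return fn

        return Tensor._make(s, (self,), bw)


def _fold_reflect(grad: np.ndarray, orig_shape: tuple, pad: int) -> np.ndarray:
    """Backward of reflect padding: accumulate mirrored positions."""
    g = grad.astype(np.float32).copy()
    for ax in (-2, -1):
        n = orig_shape[ax]
        gm = np.moveaxis(g, ax, -1)
        for i in range(pad):
            gm[..., 2 * pad - i] += gm[..., i]
            gm[..., gm.shape[-1] - 1 - 2 * pad + i] += gm[..., gm.shape[-1] - 1 - i]
        g = np.moveaxis(gm[..., pad:pad + n], -1, ax)
    return g


def cat(tensors: list, axis: int = 1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(out):
        def fn():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.grad.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(out.grad[tuple(sl)])
        return fn

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, bw)


def stack(tensors: list, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]

    def bw(out):
        def fn():
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(out.grad, i, axis=axis))
        return fn

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tensors, bw)
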