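"""A minimal reverse-mode automatic differentiation engine on NumPy arrays.

This is the numerical substrate of the segmentation network: a ``Tensor``
wraps an ndarray and records, while gradients are enabled, the closure that
propagates its output gradient to its parents.  The op set is exactly what a
3-D encoder-decoder CNN needs — broadcast-aware elementwise arithmetic,
matmul, reductions, reshapes/concat, ReLU/sigmoid — with the convolution
primitives living in :mod:`petseg.nn.conv`.

Gradient correctness is guarded by finite-difference checks in the test
suite.
"""
from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference / parameter updates)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, np.ndarray):
            self.data = data
        elif isinstance(data, np.generic):  # numpy scalar: keep its dtype
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other, self), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other, self), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other, self), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def relu(self):
        return relu(self)

    def sigmoid(self):
        return sigmoid(self)

    def sqrt(self):
        return sqrt(self)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x, like: "Tensor | None" = None) -> Tensor:
    """Wrap a scalar/array as a Tensor; scalars adopt the dtype of ``like``
    so Python-float constants never upcast a float32 graph."""
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if isinstance(like, Tensor) else np.float64
    return Tensor(np.asarray(x, dtype=dtype))


def make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    """Build an op output node; attaches the graph only when grads are on."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise ops


def add(a, b) -> Tensor:
    a, b = _wrap(a, like=b if isinstance(b, Tensor) else None), _wrap(b, like=a if isinstance(a, Tensor) else None)
    out_data = a.data + b.data

    def bwd(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    return make(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _wrap(a, like=b if isinstance(b, Tensor) else None), _wrap(b, like=a if isinstance(a, Tensor) else None)
    out_data = a.data * b.data

    def bwd(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return make(out_data, (a, b), bwd)


def div(a, b) -> Tensor:
    a, b = _wrap(a, like=b if isinstance(b, Tensor) else None), _wrap(b, like=a if isinstance(a, Tensor) else None)
    out_data = a.data / b.data

    def bwd(g):
        a.accumulate(_unbroadcast(g / b.data, a.data.shape))
        b.accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return make(out_data, (a, b), bwd)


def maximum(a, b) -> Tensor:
    """Elementwise maximum; at ties the gradient goes to the first operand."""
    a, b = _wrap(a, like=b if isinstance(b, Tensor) else None), _wrap(b, like=a if isinstance(a, Tensor) else None)
    take_a = a.data >= b.data
    out_data = np.where(take_a, a.data, b.data)

    def bwd(g):
        a.accumulate(_unbroadcast(g * take_a, a.data.shape))
        b.accumulate(_unbroadcast(g * ~take_a, b.data.shape))

    return make(out_data, (a, b), bwd)


def relu(x: Tensor) -> Tensor:
    pos = x.data > 0
    out_data = x.data * pos

    def bwd(g):
        x.accumulate(g * pos)

    return make(out_data, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x.accumulate(g * out_data * (1.0 - out_data))

    return make(out_data, (x,), bwd)


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)

    def bwd(g):
        x.accumulate(g * 0.5 / out_data)

    return make(out_data, (x,), bwd)


# ---------------------------------------------------------------------------
# reductions / shape ops


def tsum(x: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = np.asarray(x.data.sum(axis=axis, keepdims=keepdims))

    def bwd(g):
        if axis is None:
            grad = np.broadcast_to(g, x.data.shape)
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axes)
            grad = np.broadcast_to(gg, x.data.shape)
        x.accumulate(grad.astype(x.data.dtype, copy=False).copy())

    return make(out_data, (x,), bwd)


def tmean(x: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = x.data.size
    else:
        axes = (axis,) if np.isscalar(axis) else tuple(axis)
        n = int(np.prod([x.data.shape[a] for a in axes]))
    return mul(tsum(x, axis, keepdims), 1.0 / n)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    out_data = x.data.reshape(shape)

    def bwd(g):
        x.accumulate(g.reshape(old))

    return make(out_data, (x,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        a.accumulate(g @ b.data.T)
        b.accumulate(a.data.T @ g)

    return make(out_data, (a, b), bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t.accumulate(g[tuple(sl)])

    return make(out_data, tuple(tensors), bwd)
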