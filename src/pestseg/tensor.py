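"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps a ``float64`` numpy
array and records, for each produced value, its parents and a closure that
routes the upstream gradient to them.  ``Tensor.backward`` walks the tape in
reverse topological order.  Only the operations the segmentation network
needs are provided; convolution and the selective scan register themselves
as custom primitives via :func:`make_node`.

All arrays are channels-last and double precision.  Broadcasting follows
numpy semantics; gradients of broadcast operands are summed back to the
operand's shape.
"""
from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable tape recording (inference / metric evaluation)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ info
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, *shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    # ------------------------------------------------------------- autograd
    def backward(self, grad: np.ndarray | None = None):
        if not self.requires_grad:
            raise RuntimeError("backward on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        # iterative post-order topological sort
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def make_node(data, parents, backward) -> Tensor:
    """Create a graph node; ``backward(grad)`` must accumulate into parents."""
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def accum(t: Tensor, g: np.ndarray):
    """Accumulate a gradient contribution into a tensor."""
    if not t.requires_grad:
        return
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` over the axes that were broadcast to reach ``g.shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ------------------------------------------------------------------ binary ops
def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        accum(a, _unbroadcast(g, a.data.shape))
        accum(b, _unbroadcast(g, b.data.shape))

    return make_node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        accum(a, _unbroadcast(g * b.data, a.data.shape))
        accum(b, _unbroadcast(g * a.data, b.data.shape))

    return make_node(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        accum(a, _unbroadcast(g / b.data, a.data.shape))
        accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return make_node(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        accum(a, g * p * a.data ** (p - 1))

    return make_node(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if b.data.ndim == 1:
            ga = np.multiply.outer(g, b.data) if a.data.ndim > 1 else g * b.data
            gb = (a.data * g[..., None]).reshape(-1, b.data.shape[0]).sum(0) \
                if a.data.ndim > 1 else g * a.data
            accum(a, _unbroadcast(ga, a.data.shape))
            accum(b, _unbroadcast(gb, b.data.shape))
            return
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        accum(a, _unbroadcast(ga, a.data.shape))
        accum(b, _unbroadcast(gb, b.data.shape))

    return make_node(out_data, (a, b), backward)


# ------------------------------------------------------------------ unary ops
def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        accum(a, g * out_data)

    return make_node(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        accum(a, g / a.data)

    return make_node(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        accum(a, g * out_data * (1.0 - out_data))

    return make_node(out_data, (a,), backward)


def silu(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        accum(a, g * (s + a.data * s * (1.0 - s)))

    return make_node(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        accum(a, g * (a.data > 0))

    return make_node(out_data, (a,), backward)


def softplus(a) -> Tensor:
    a = as_tensor(a)
    # overflow-safe: softplus(x) = max(x,0) + log1p(exp(-|x|))
    out_data = np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data)))

    def backward(g):
        accum(a, g / (1.0 + np.exp(-a.data)))

    return make_node(out_data, (a,), backward)


# ------------------------------------------------------------------ reductions
def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        accum(a, np.broadcast_to(g, a.data.shape).copy())

    return make_node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def tmax(a, axis, keepdims=False) -> Tensor:
    """Max along one axis; gradient flows to (first) argmax positions."""
    a = as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)
    expanded = out_data if keepdims else np.expand_dims(out_data, axis)
    hit = a.data == expanded
    # split ties evenly so the gradient stays well-defined
    weights = hit / hit.sum(axis=axis, keepdims=True)

    def backward(g):
        gexp = g if keepdims else np.expand_dims(g, axis)
        accum(a, gexp * weights)

    return make_node(out_data, (a,), backward)


# ------------------------------------------------------------------ shape ops
def reshape(a, *shape) -> Tensor:
    a = as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    out_data = a.data.reshape(shape)
    orig = a.data.shape

    def backward(g):
        accum(a, g.reshape(orig))

    return make_node(out_data, (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.transpose(axes)
    inv = None if axes is None else np.argsort(axes)

    def backward(g):
        accum(a, g.transpose(inv) if inv is not None else g.transpose())

    return make_node(out_data, (a,), backward)


def concatenate(tensors, axis=-1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            accum(t, piece)

    return make_node(out_data, tuple(tensors), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        accum(a, ga)

    return make_node(out_data, (a,), backward)


def take_rows(a, indices: np.ndarray, axis: int = 1) -> Tensor:
    """Permute/gather along ``axis`` with integer ``indices`` (scatter-add backward)."""
    a = as_tensor(a)
    out_data = np.take(a.data, indices, axis=axis)

    def backward(g):
        ga = np.zeros_like(a.data)
        sl = [slice(None)] * a.data.ndim
        sl[axis] = indices
        np.add.at(ga, tuple(sl), g)
        accum(a, ga)

    return make_node(out_data, (a,), backward)


# ------------------------------------------------------------------ softmax
def log_softmax(a, axis=-1) -> Tensor:
    a = as_tensor(a)
    shift = np.max(a.data, axis=axis, keepdims=True)  # constant; no gradient needed
    z = a - shift
    return z - log(tsum(exp(z), axis=axis, keepdims=True))


def softmax(a, axis=-1) -> Tensor:
    return exp(log_softmax(a, axis=axis))
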