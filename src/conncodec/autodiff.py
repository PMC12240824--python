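"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the linear codec model and its loss terms
need: broadcast arithmetic, matmul, reductions, sqrt, relu, reshape and
transpose. Gradients are accumulated by a topological backward sweep.
Every op is exercised against central finite differences in the test suite.

The helper functions (``add``, ``matmul``, ``sum_``, ...) dispatch on type:
given plain ndarrays they fall through to NumPy, so loss code written against
this module runs identically with and without gradient tracking.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "matmul", "sum_", "mean", "sqrt", "relu", "reshape",
           "transpose", "maximum_const"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accum(-g if a.shape == g.shape else _unbroadcast(-g, a.shape))
        return Tensor(-self.value, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, pow_(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), pow_(self, -1.0))

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'yes' if self.grad is not None else 'no'})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_t(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def add(a, b):
    if not _is_t(a, b):
        return np.add(a, b)
    a, b = _wrap(a), _wrap(b)
    out_val = a.value + b.value

    def bwd(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    return Tensor(out_val, parents=(a, b), backward=bwd)


def mul(a, b):
    if not _is_t(a, b):
        return np.multiply(a, b)
    a, b = _wrap(a), _wrap(b)
    out_val = a.value * b.value

    def bwd(g):
        a._accum(_unbroadcast(g * b.value, a.shape))
        b._accum(_unbroadcast(g * a.value, b.shape))

    return Tensor(out_val, parents=(a, b), backward=bwd)


def pow_(a, p: float):
    if not _is_t(a):
        return np.power(a, p)
    out_val = np.power(a.value, p)

    def bwd(g):
        a._accum(g * p * np.power(a.value, p - 1.0))

    return Tensor(out_val, parents=(a,), backward=bwd)


def matmul(a, b):
    if not _is_t(a, b):
        return np.matmul(a, b)
    a, b = _wrap(a), _wrap(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("autodiff matmul supports 2-D operands only")
    out_val = a.value @ b.value

    def bwd(g):
        a._accum(g @ b.value.T)
        b._accum(a.value.T @ g)

    return Tensor(out_val, parents=(a, b), backward=bwd)


def sum_(a, axis=None, keepdims: bool = False):
    if not _is_t(a):
        return np.sum(a, axis=axis, keepdims=keepdims)
    out_val = np.sum(a.value, axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.shape).copy())
            return
        g2 = g
        if not keepdims:
            g2 = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g2, a.shape).copy())

    return Tensor(out_val, parents=(a,), backward=bwd)


def mean(a, axis=None, keepdims: bool = False):
    if not _is_t(a):
        return np.mean(a, axis=axis, keepdims=keepdims)
    if axis is None:
        n = a.value.size
    else:
        n = a.shape[axis]
    return sum_(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def sqrt(a):
    if not _is_t(a):
        return np.sqrt(a)
    return pow_(a, 0.5)


def relu(a):
    if not _is_t(a):
        return np.maximum(a, 0.0)
    out_val = np.maximum(a.value, 0.0)
    mask = (a.value > 0.0).astype(np.float64)

    def bwd(g):
        a._accum(g * mask)

    return Tensor(out_val, parents=(a,), backward=bwd)


def maximum_const(a, c: float):
    """Elementwise max(a, c) for a constant c (c is not differentiated)."""
    if not _is_t(a):
        return np.maximum(a, c)
    out_val = np.maximum(a.value, c)
    mask = (a.value > c).astype(np.float64)

    def bwd(g):
        a._accum(g * mask)

    return Tensor(out_val, parents=(a,), backward=bwd)


def reshape(a, shape):
    if not _is_t(a):
        return np.reshape(a, shape)
    old = a.shape
    out_val = a.value.reshape(shape)

    def bwd(g):
        a._accum(g.reshape(old))

    return Tensor(out_val, parents=(a,), backward=bwd)


def transpose(a):
    if not _is_t(a):
        return np.transpose(a)
    out_val = a.value.T

    def bwd(g):
        a._accum(g.T)

    return Tensor(out_val, parents=(a,), backward=bwd)


def value_of(x) -> np.ndarray:
    """Underlying ndarray of a Tensor, or the array itself."""
    return x.value if isinstance(x, Tensor) else np.asarray(x)
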