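"""Minimal vectorised reverse-mode automatic differentiation on NumPy arrays.

The simulator needs gradients of a structural loss with respect to every
force-field parameter, obtained by backpropagating through thousands of
integrator steps.  This module provides exactly the operations that the
force calculation, integrator and loss require: elementwise arithmetic,
reductions, gather / scatter-add, vector norms and cross products, and
matrix multiplication.  Each :class:`Tensor` records its parents and a
closure that propagates the output cotangent to them; ``backward`` runs a
topological sweep over the recorded graph.

Design notes
------------
* Operations accept plain numbers / ndarrays and lift them to constants.
* Broadcasting is supported; cotangents are summed back to parent shapes.
* The helper functions (:func:`norm`, :func:`cross`, :func:`gather`,
  :func:`scatter_add`, ...) dispatch on their argument types, so numerical
  code written against them runs unchanged on raw ndarrays (fast,
  gradient-free production path) or on Tensors (recorded training path).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor", "astensor", "asarray", "is_tensor",
    "norm", "cross", "gather", "scatter_add", "matmul",
    "sqrt", "tsum", "mean", "stack", "log1p",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with recorded provenance for reverse-mode AD."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph traversal ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float).reshape(self.data.shape)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free interior cotangents to bound memory over long rollouts
            if node._parents and node is not self:
                node.grad = None

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=float), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- basic properties ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        o = astensor(other)
        out = Tensor(self.data + o.data, parents=(self, o))
        if out.requires_grad:
            def bwd(g, a=self, b=o):
                if a.requires_grad:
                    a._accum(g)
                if b.requires_grad:
                    b._accum(g)
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        o = astensor(other)
        out = Tensor(self.data * o.data, parents=(self, o))
        if out.requires_grad:
            def bwd(g, a=self, b=o):
                if a.requires_grad:
                    a._accum(g * b.data)
                if b.requires_grad:
                    b._accum(g * a.data)
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = astensor(other)
        out = Tensor(self.data / o.data, parents=(self, o))
        if out.requires_grad:
            def bwd(g, a=self, b=o):
                if a.requires_grad:
                    a._accum(g / b.data)
                if b.requires_grad:
                    b._accum(-g * a.data / (b.data * b.data))
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** exponent, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, n=exponent: a._accum(
                g * n * a.data ** (n - 1))
        return out

    # -- indexing -----------------------------------------------------------

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        if out.requires_grad:
            # scatter straight into the parent's grad buffer: the parent may
            # be the multi-million-entry parameter table, gathered from at
            # every integrator step
            def bwd(g, a=self, i=idx):
                if a.grad is None:
                    a.grad = np.zeros_like(a.data)
                np.add.at(a.grad, i, g)
            out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out


# -- constructors / dispatch helpers ----------------------------------------

def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def asarray(x) -> np.ndarray:
    """The underlying ndarray (detached view) of a Tensor or array."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _any_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


# -- elementwise / reduction ops --------------------------------------------

def sqrt(x):
    if not is_tensor(x):
        return np.sqrt(x)
    out = Tensor(np.sqrt(x.data), parents=(x,))
    if out.requires_grad:
        out._backward = lambda g, a=x, d=out.data: a._accum(g / (2.0 * d))
    return out


def log1p(x):
    if not is_tensor(x):
        return np.log1p(x)
    out = Tensor(np.log1p(x.data), parents=(x,))
    if out.requires_grad:
        out._backward = lambda g, a=x: a._accum(g / (1.0 + a.data))
    return out


def tsum(x, axis=None):
    """Sum (named ``tsum`` to avoid shadowing builtins)."""
    if not is_tensor(x):
        return np.sum(x, axis=axis)
    out = Tensor(np.sum(x.data, axis=axis), parents=(x,))
    if out.requires_grad:
        def bwd(g, a=x, ax=axis):
            if ax is None:
                a._accum(np.broadcast_to(g, a.data.shape))
            else:
                a._accum(np.broadcast_to(np.expand_dims(g, ax), a.data.shape))
        out._backward = bwd
    return out


def mean(x, axis=None):
    if not is_tensor(x):
        return np.mean(x, axis=axis)
    n = x.data.size if axis is None else x.data.shape[axis]
    return tsum(x, axis=axis) / float(n)


def norm(x, axis=-1):
    """Euclidean norm along ``axis`` (differentiable)."""
    if not is_tensor(x):
        return np.linalg.norm(x, axis=axis)
    return sqrt(tsum(x * x, axis=axis))


def cross(a, b):
    """Cross product along the last axis."""
    if not _any_tensor(a, b):
        return np.cross(a, b)
    a, b = astensor(a), astensor(b)
    out = Tensor(np.cross(a.data, b.data), parents=(a, b))
    if out.requires_grad:
        def bwd(g, x=a, y=b):
            if x.requires_grad:
                x._accum(np.cross(y.data, g))
            if y.requires_grad:
                y._accum(np.cross(g, x.data))
        out._backward = bwd
    return out


def gather(x, idx):
    """``x[idx]`` with integer index arrays (scatter-add on backward)."""
    if not is_tensor(x):
        return x[idx]
    return x[idx]


def scatter_add(values, idx, n):
    """Accumulate rows of ``values`` into an ``(n, ...)`` array at ``idx``.

    ``idx`` is a 1-D integer array, one entry per row of ``values``.
    """
    if not is_tensor(values):
        out = np.zeros((n,) + values.shape[1:], dtype=float)
        np.add.at(out, idx, values)
        return out
    data = np.zeros((n,) + values.data.shape[1:], dtype=float)
    np.add.at(data, idx, values.data)
    out = Tensor(data, parents=(values,))
    if out.requires_grad:
        out._backward = lambda g, v=values, i=idx: v._accum(g[i])
    return out


def matmul(a, b):
    """2-D matrix product; either operand may be a constant ndarray."""
    if not _any_tensor(a, b):
        return np.asarray(a) @ np.asarray(b)
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))
    if out.requires_grad:
        def bwd(g, x=a, y=b):
            if x.requires_grad:
                x._accum(g @ y.data.T)
            if y.requires_grad:
                y._accum(x.data.T @ g)
        out._backward = bwd
    return out


def stack(parts, axis=0):
    if not _any_tensor(*parts):
        return np.stack(parts, axis=axis)
    parts = [astensor(p) for p in parts]
    out = Tensor(np.stack([p.data for p in parts], axis=axis), parents=tuple(parts))
    if out.requires_grad:
        def bwd(g, ps=parts, ax=axis):
            for k, p in enumerate(ps):
                if p.requires_grad:
                    p._accum(np.take(g, k, axis=ax))
        out._backward = bwd
    return out
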