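"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the GraphADT model needs: dense matrix
products, broadcasting arithmetic, sigmoid/relu/log/exp, reductions, row
indexing, concatenation/stacking and a differentiable linear solve (used by
the personalised-PageRank pooling view).  All tensors are float64; the graph
is built eagerly and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np

_grad_enabled = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        out = self._make(self.data.T, (self,))
        if out.requires_grad:
            def bw(g):
                return (g.T,)
            out._backward = bw
        return out

    @staticmethod
    def _make(data: np.ndarray, parents: tuple) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = self._make(self.data + other.data, (self, other))
        if out.requires_grad:
            sa, sb = self.data.shape, other.data.shape
            out._backward = lambda g: (_unbroadcast(g, sa), _unbroadcast(g, sb))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = self._make(self.data * other.data, (self, other))
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = self._make(self.data / other.data, (self, other))
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape),
            )
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self._make(self.data @ other.data, (self, other))
        if out.requires_grad:
            a, b = self, other
            def bw(g):
                ga = g @ b.data.T if b.data.ndim == 2 else np.outer(g, b.data)
                gb = a.data.T @ g
                return ga, gb
            out._backward = bw
        return out

    def __pow__(self, exponent: float):
        out = self._make(self.data ** exponent, (self,))
        if out.requires_grad:
            a = self
            out._backward = lambda g: (g * exponent * a.data ** (exponent - 1),)
        return out

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out = self._make(np.exp(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: (g * out.data,)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,))
        if out.requires_grad:
            a = self
            out._backward = lambda g: (g / a.data,)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = self._make(s, (self,))
        if out.requires_grad:
            out._backward = lambda g: (g * out.data * (1.0 - out.data),)
        return out

    def relu(self):
        out = self._make(np.maximum(self.data, 0.0), (self,))
        if out.requires_grad:
            mask = self.data > 0
            out._backward = lambda g: (g * mask,)
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            shape = self.data.shape
            def bw(g):
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                return (np.broadcast_to(g, shape).copy(),)
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = self._make(out_data, (self,))
        if out.requires_grad:
            a = self
            def bw(g):
                g = np.asarray(g)
                full = out_data if keepdims or axis is None else np.expand_dims(out_data, axis)
                gg = g if keepdims or axis is None else np.expand_dims(g, axis)
                mask = (a.data == full)
                # split gradient across ties to keep the op well defined
                counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
                return (mask * gg / counts,)
            out._backward = bw
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            orig = self.data.shape
            out._backward = lambda g: (g.reshape(orig),)
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,))
        if out.requires_grad:
            shape = self.data.shape
            def bw(g):
                full = np.zeros(shape)
                np.add.at(full, idx, g)
                return (full,)
            out._backward = bw
        return out

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad = parent.grad + g

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        def bw(g):
            return tuple(np.moveaxis(g, axis, 0))
        out._backward = bw
    return out


def solve(A: Tensor, b: Tensor) -> Tensor:
    """Differentiable dense solve x = A^{-1} b (b a vector or matrix).

    Backward uses the adjoint identities dL/db = A^{-T} g and
    dL/dA = -A^{-T} g x^T.
    """
    A, b = as_tensor(A), as_tensor(b)
    x = np.linalg.solve(A.data, b.data)
    out = Tensor._make(x, (A, b))
    if out.requires_grad:
        def bw(g):
            gb = np.linalg.solve(A.data.T, g)
            if x.ndim == 1:
                gA = -np.outer(gb, x)
            else:
                gA = -gb @ x.T
            return gA, gb
        out._backward = bw
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    t = as_tensor(t)
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))  # detached max
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(t: Tensor, axis: int = -1) -> Tensor:
    t = as_tensor(t)
    m = Tensor(t.data.max(axis=axis, keepdims=True))
    return (t - m).exp().sum(axis=axis, keepdims=True).log() + m
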