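"""Minimal reverse-mode automatic differentiation over numpy arrays.

The survival networks in this package need gradients of the composite
Cox-partial-likelihood + ranking loss with respect to network weights.
This module provides a small tape-based ``Tensor`` supporting exactly the
operations those architectures use (affine maps, gate nonlinearities,
elementwise arithmetic, reductions, concatenation, slicing). Gradients
are accumulated by topological traversal of the recorded graph; every
primitive is broadcast-aware.

Correctness is pinned by central-finite-difference tests rather than by
construction, so keep primitives few and boring.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "sigmoid", "tanh", "relu", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # Sum leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Sum axes that were size-1 in the original.
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the local backward rule that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- primitives --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)
        out = Tensor(self.data ** p, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), requires_grad=self.requires_grad,
                     _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * val)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out


def tanh(x: Tensor) -> Tensor:
    val = np.tanh(x.data)
    out = Tensor(val, requires_grad=x.requires_grad, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * (1.0 - val * val))

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    val = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(val, requires_grad=x.requires_grad, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * val * (1.0 - val))

    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), requires_grad=x.requires_grad, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * mask)

    out._backward = bw
    return out


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1-D tensors of equal length into a 2-D tensor (rows)."""
    return concatenate([t.reshape(1, -1) for t in tensors], axis=0)
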