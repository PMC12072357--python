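"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the model needs: affine maps, ReLU,
sigmoid, elementwise arithmetic, log, clip, concatenation, transpose,
and sum/mean reductions.  Gradients flow to every ``Tensor`` created
with ``requires_grad=True`` (parameters) and to input tensors, which is
what integrated-gradients attribution relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over broadcast axes so it matches `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the graph bookkeeping needed for backprop."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(value, parents, backward) -> "Tensor":
        out = Tensor(value)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.value.shape

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g, a=self, b=other):
            return (_unbroadcast(g, a.value.shape), _unbroadcast(g, b.value.shape))

        return Tensor._make(self.value + other.value, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._coerce(other)

        def backward(g, a=self, b=other):
            return (_unbroadcast(g, a.value.shape), _unbroadcast(-g, b.value.shape))

        return Tensor._make(self.value - other.value, (self, other), backward)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g, a=self, b=other):
            return (
                _unbroadcast(g * b.value, a.value.shape),
                _unbroadcast(g * a.value, b.value.shape),
            )

        return Tensor._make(self.value * other.value, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(g, a=self, b=other):
            return (g @ b.value.T, a.value.T @ g)

        return Tensor._make(self.value @ other.value, (self, other), backward)

    # -- nonlinearities and reshaping ---------------------------------------

    def relu(self):
        mask = self.value > 0

        def backward(g, m=mask):
            return (g * m,)

        return Tensor._make(np.where(mask, self.value, 0.0), (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.value))

        def backward(g, s=s):
            return (g * s * (1.0 - s),)

        return Tensor._make(s, (self,), backward)

    def log(self):
        def backward(g, a=self):
            return (g / a.value,)

        return Tensor._make(np.log(self.value), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through only inside the range."""
        inside = (self.value >= lo) & (self.value <= hi)

        def backward(g, m=inside):
            return (g * m,)

        return Tensor._make(np.clip(self.value, lo, hi), (self,), backward)

    def square(self):
        def backward(g, a=self):
            return (2.0 * g * a.value,)

        return Tensor._make(self.value**2, (self,), backward)

    @property
    def T(self):
        def backward(g):
            return (g.T,)

        return Tensor._make(self.value.T, (self,), backward)

    def sum(self):
        def backward(g, a=self):
            return (np.broadcast_to(g, a.value.shape).copy(),)

        return Tensor._make(self.value.sum(), (self,), backward)

    def mean(self):
        n = self.value.size

        def backward(g, a=self, n=n):
            return (np.broadcast_to(g / n, a.value.shape).copy(),)

        return Tensor._make(self.value.mean(), (self,), backward)

    # -- backward pass ------------------------------------------------------

    def backward(self, grad=None):
        """Accumulate gradients of this (scalar) tensor w.r.t. the graph."""
        if grad is None:
            grad = np.ones_like(self.value)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative postorder; graphs can be deep-ish
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient back."""
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors), backward
    )
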