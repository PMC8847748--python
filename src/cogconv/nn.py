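"""Minimal reverse-mode automatic differentiation on numpy arrays.

The predictor in :mod:`cogconv.model` is a small, fixed architecture
(a five-layer perceptron, a single-layer LSTM unrolled over at most two
visits, and one scaled dot-product attention block), so a compact
tape-based engine is sufficient: every operation records its parents and
a closure that pushes the upstream gradient back onto them.  All values
are ``float64`` and every computation is deterministic, which the
training contract of the package relies on.

Only the operations the model needs are provided.  Gradients are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat_cols", "softmax_rows", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph holding a float64 array."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        value: np.ndarray | float,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph machinery --------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.value.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order; graphs can be deep at 1000 epochs
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------

    @staticmethod
    def _lift(other: "Tensor | np.ndarray | float") -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, (self, other))
        out._backward = lambda g: (self._accumulate(g), other._accumulate(g))
        return out

    __radd__ = __add__

    def __sub__(self, other):
        other = self._lift(other)
        out = Tensor(self.value - other.value, (self, other))
        out._backward = lambda g: (self._accumulate(g), other._accumulate(-g))
        return out

    def __rsub__(self, other):
        return self._lift(other) - self

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, (self, other))
        out._backward = lambda g: (
            self._accumulate(g * other.value),
            other._accumulate(g * self.value),
        )
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value @ other.value, (self, other))
        out._backward = lambda g: (
            self._accumulate(g @ other.value.T),
            other._accumulate(self.value.T @ g),
        )
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.value > 0
        out = Tensor(np.where(mask, self.value, 0.0), (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        s = 0.5 * (np.tanh(0.5 * self.value) + 1.0)  # overflow-safe logistic
        out = Tensor(s, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.value)
        out = Tensor(t, (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - t * t))
        return out

    def softplus(self):
        # log(1 + e^x), stable for large |x|
        v = np.logaddexp(0.0, self.value)
        s = 0.5 * (np.tanh(0.5 * self.value) + 1.0)
        out = Tensor(v, (self,))
        out._backward = lambda g: self._accumulate(g * s)
        return out

    # -- reductions and shape ops -----------------------------------------

    def sum(self, axis: int | None = None, keepdims: bool = False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.value.shape))

        out._backward = bw
        return out

    def mean(self):
        return self.sum() * (1.0 / self.value.size)

    def slice_cols(self, start: int, stop: int):
        out = Tensor(self.value[:, start:stop], (self,))

        def bw(g):
            full = np.zeros_like(self.value)
            full[:, start:stop] = g
            self._accumulate(full)

        out._backward = bw
        return out

    @property
    def T(self):
        out = Tensor(self.value.T, (self,))
        out._backward = lambda g: self._accumulate(g.T)
        return out


def concat_cols(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 1."""
    out = Tensor(np.concatenate([t.value for t in tensors], axis=1), tuple(tensors))
    widths = [t.value.shape[1] for t in tensors]

    def bw(g):
        ofs = 0
        for t, w in zip(tensors, widths):
            t._accumulate(g[:, ofs : ofs + w])
            ofs += w

    out._backward = bw
    return out


def softmax_rows(x: Tensor) -> Tensor:
    """Row-wise softmax of a 2-D tensor."""
    z = x.value - x.value.max(axis=1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=1, keepdims=True)
    out = Tensor(y, (x,))
    out._backward = lambda g: x._accumulate(y * (g - (g * y).sum(axis=1, keepdims=True)))
    return out


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
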