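"""Compact reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the fragment-probability models: tensors wrap
ndarrays, every operation records its parents and a gradient closure,
and ``backward`` walks the tape in reverse topological order.  Gradients
are verified against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        value: ArrayLike,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], Sequence[np.ndarray]]] = None,
        requires_grad: bool = False,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph -----------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.value.size != 1:
                raise ValueError("implicit gradient only for scalar outputs")
            grad = np.ones_like(self.value)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
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
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy()
                else:
                    parent.grad = parent.grad + pgrad

    def zero_grad(self) -> None:
        self.grad = None

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.value.shape

    def item(self) -> float:
        return float(self.value)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.value + other.value,
            (self, other),
            lambda g: (
                _unbroadcast(g, self.value.shape),
                _unbroadcast(g, other.value.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.value * other.value,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.value, self.value.shape),
                _unbroadcast(g * self.value, other.value.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.value / other.value,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.value, self.value.shape),
                _unbroadcast(-g * self.value / other.value**2, other.value.shape),
            ),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.value @ other.value,
            (self, other),
            lambda g: (g @ other.value.T, self.value.T @ g),
        )

    @property
    def T(self) -> "Tensor":
        return Tensor(self.value.T, (self,), lambda g: (g.T,))


def as_tensor(x: Union[Tensor, ArrayLike]) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(value: np.ndarray) -> Tensor:
    return Tensor(value, requires_grad=True)


# -- elementwise functions ------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.value > 0
    return Tensor(np.where(mask, x.value, 0.0), (x,), lambda g: (g * mask,))


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.value)
    return Tensor(y, (x,), lambda g: (g * (1 - y**2),))


def softplus(x: Tensor) -> Tensor:
    y = np.logaddexp(0.0, x.value)
    sig = 1.0 / (1.0 + np.exp(-x.value))
    return Tensor(y, (x,), lambda g: (g * sig,))


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.value)
    return Tensor(y, (x,), lambda g: (g * y,))


def power(x: Tensor, p: float, eps: float = 1e-12) -> Tensor:
    """(x + eps)^p; eps keeps the p < 1 gradient finite at zero intensity."""
    base = x.value + eps
    y = base**p
    return Tensor(y, (x,), lambda g: (g * p * base ** (p - 1.0),))


def sqrt(x: Tensor, eps: float = 1e-24) -> Tensor:
    y = np.sqrt(x.value + eps)
    return Tensor(y, (x,), lambda g: (g * 0.5 / y,))


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    y = x.value.sum(axis=axis, keepdims=keepdims)

    def back(g):
        if axis is None:
            return (np.broadcast_to(g, x.value.shape).copy(),)
        gg = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(gg, x.value.shape).copy(),)

    return Tensor(y, (x,), back)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.value.size if axis is None else x.value.shape[axis]
    return tsum(x, axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    vals = [t.value for t in tensors]
    y = np.concatenate(vals, axis=axis)
    sizes = [v.shape[axis] for v in vals]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(y, tuple(tensors), back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.value - x.value.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return ((g - dot) * y,)

    return Tensor(y, (x,), back)


def l2_normalize(x: Tensor, eps: float = 1e-24) -> Tensor:
    """x / ||x||_2 along the last axis."""
    norm = sqrt(tsum(x * x, axis=-1, keepdims=True), eps=eps)
    return x / norm


# -- optimiser -------------------------------------------------------------

class Adam:
    """Standard Adam on a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
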