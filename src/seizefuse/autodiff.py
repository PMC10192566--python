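"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd style, but vectorized: every
node wraps an ndarray and records a closure that accumulates gradients
into its parents.  It provides exactly the operations the two-branch
seizure-prediction networks need (dense algebra, 1-D/2-D convolution,
pooling, LSTM building blocks, softmax/cross-entropy, and the gradient
reversal connector used for episode-adversarial training).

All arithmetic is float64.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "gradient_reversal", "softmax", "concat", "stack_time"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._node(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- elementwise nonlinearities -------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - y * y))

        return Tensor._node(y, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accum(g * y * (1.0 - y))

        return Tensor._node(y, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._node(self.data * mask, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._node(np.log(self.data), (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._node(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(*inv))

        return Tensor._node(self.data.transpose(*axes), (self,), backward)

    def index0(self, i: int):
        """Select slice i along axis 0 (used to step through time)."""

        def backward(g):
            full = np.zeros_like(self.data)
            full[i] = g
            self._accum(full)

        return Tensor._node(self.data[i], (self,), backward)

    def narrow(self, axis: int, start: int, length: int):
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)

        def backward(g):
            full = np.zeros_like(self.data)
            full[sl] = g
            self._accum(full)

        return Tensor._node(self.data[sl], (self,), backward)

    def flip0(self):
        """Reverse along axis 0 (backward direction of a Bi-LSTM)."""

        def backward(g):
            self._accum(g[::-1])

        return Tensor._node(self.data[::-1].copy(), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def gather_rows(self, idx: np.ndarray):
        """out[i] = self[i, idx[i]] for a 2-D tensor."""
        idx = np.asarray(idx, dtype=np.intp)
        rows = np.arange(self.data.shape[0])

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (rows, idx), g)
            self._accum(full)

        return Tensor._node(self.data[rows, idx], (self,), backward)

    # -- backprop driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


# -- free functions -----------------------------------------------------------

def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        t._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return Tensor._node(y, (t,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def stack_time(tensors) -> Tensor:
    """Stack a list of equally-shaped tensors along a new leading axis."""

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(g[i])

    return Tensor._node(np.stack([t.data for t in tensors]), tuple(tensors), backward)


def gradient_reversal(t: Tensor, lambda_grl: float = 1.0) -> Tensor:
    """Identity in the forward pass; scales the backward gradient by -lambda_grl.

    Placed between a feature extractor and an episode discriminator it turns
    the discriminator's minimization into feature-level confusion: the
    discriminator still learns to tell episodes apart, while the features
    receive the reversed gradient and drift toward episode invariance.
    """

    def backward(g):
        t._accum(-lambda_grl * g)

    return Tensor._node(t.data.copy(), (t,), backward)
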