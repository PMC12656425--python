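"""Minimal reverse-mode automatic differentiation on numpy arrays.

This tape-based engine provides exactly the operator set the toolkit's
networks need (dense layers, 1-D convolution via framing, multi-head
attention, batch/layer normalisation, softmax cross-entropy and the
NT-Xent loss).  Everything is float64, which keeps finite-difference
gradient checks tight.

Only the basics are implemented: broadcasting is supported on
element-wise ops and matmul batch dimensions; gradients accumulate with
``+=`` over a topologically sorted tape.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # ---------------------------------------------------------------- infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Run reverse-mode accumulation from this (scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t._accumulate(g)
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    # ------------------------------------------------------------ operators
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _needs_tape(self, *others: "Tensor") -> bool:
        return any(
            t.requires_grad or t._backward is not None for t in (self, *others)
        )

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if self._needs_tape(*[p for p in parents if isinstance(p, Tensor)]):
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    def __add__(self, other):
        other = self._lift(other)
        data = self.data + other.data

        def backward(g):
            return [
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            ]

        return self._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return [(self, -g)]

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        data = self.data * other.data

        def backward(g):
            return [
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            ]

        return self._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        data = self.data / other.data

        def backward(g):
            return [
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            ]

        return self._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        data = self.data**p

        def backward(g):
            return [(self, g * p * self.data ** (p - 1))]

        return self._make(data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                return [(self, g * b), (other, g * a)]
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.outer(a, g) if b.ndim == 2 else a[:, None] * g
                return [(self, _unbroadcast(ga, a.shape)), (other, _unbroadcast(gb, b.shape))]
            if b.ndim == 1:
                ga = np.expand_dims(g, -1) * b
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim == 2 else (a * np.expand_dims(g, -1)).sum(tuple(range(a.ndim - 1)))
                return [(self, _unbroadcast(ga, a.shape)), (other, _unbroadcast(gb, b.shape))]
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return [(self, _unbroadcast(ga, a.shape)), (other, _unbroadcast(gb, b.shape))]

        return self._make(data, (self, other), backward)

    # ------------------------------------------------------- unary functions
    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            return [(self, g * data)]

        return self._make(data, (self,), backward)

    def log(self):
        def backward(g):
            return [(self, g / self.data)]

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self**0.5

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return [(self, g * mask)]

        return self._make(self.data * mask, (self,), backward)

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g):
            return [(self, g * (1.0 - data**2))]

        return self._make(data, (self,), backward)

    # ---------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else axis
                for ax in sorted(a % self.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            return [(self, np.broadcast_to(g, self.shape).copy())]

        return self._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in ((axis,) if isinstance(axis, int) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        data = self.data.reshape(shape)

        def backward(g):
            return [(self, g.reshape(orig))]

        return self._make(data, (self,), backward)

    def permute(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            return [(self, g.transpose(inv))]

        return self._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.permute(*axes)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return [(self, full)]

        return self._make(data, (self,), backward)


# ------------------------------------------------------------------ helpers

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    out = Tensor(data)
    if any(t.requires_grad or t._backward is not None for t in tensors):
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def frame1d(x: Tensor, width: int, stride: int) -> Tensor:
    """Frame a (B, T, C) tensor into (B, n_frames, width * C) windows.

    The forward pass copies strided windows; the backward pass
    scatter-adds the window gradients back onto the sequence.
    """
    B, T, C = x.shape
    n = 1 + (T - width) // stride
    idx = stride * np.arange(n)[:, None] + np.arange(width)[None, :]  # (n, width)
    data = x.data[:, idx, :].reshape(B, n, width * C)

    def backward(g):
        g = g.reshape(B, n, width, C)
        full = np.zeros_like(x.data)
        np.add.at(full, (slice(None), idx), g)
        return [(x, full)]

    out = Tensor(data)
    if x.requires_grad or x._backward is not None:
        out._parents = (x,)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (max is detached)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    return (x - shift).exp().sum(axis=axis, keepdims=True).log() + shift
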