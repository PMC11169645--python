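"""Reverse-mode automatic differentiation on numpy arrays.

The models in this package (adaptive graph learning, graph convolutions,
gated recurrent units, channel attention) are trained end to end, so every
operation between the raw time-series windows and the classification loss
must be differentiable.  This module provides the small tensor engine the
rest of the package builds on: a :class:`Tensor` wraps a float64 numpy
array, records the operations applied to it, and :meth:`Tensor.backward`
accumulates vector-Jacobian products through the recorded graph.

Only the primitives the models need are implemented (broadcast arithmetic,
batched matmul, elementwise nonlinearities, reductions, indexing,
concatenation).  Everything is float64; gradients are checked against
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack", "softmax_lastdim", "log_softmax_lastdim"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _make(data: np.ndarray, parents) -> "Tensor":
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    out._parents = tuple((p, fn) for p, fn in parents if p.requires_grad)
    out.requires_grad = bool(out._parents)
    return out


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar requires an explicit grad")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs from long sequences recurse deeply
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            g = node.grad
            for parent, vjp in node._parents:
                pg = vjp(g)
                parent.grad = pg if parent.grad is None else parent.grad + pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        return _make(
            a.data + b.data,
            [
                (a, lambda g: _unbroadcast(g, a.data.shape)),
                (b, lambda g: _unbroadcast(g, b.data.shape)),
            ],
        )

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        return _make(
            a.data * b.data,
            [
                (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
                (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return (-self) + other

    def __pow__(self, power: float):
        a = self
        p = float(power)
        return _make(
            a.data**p,
            [(a, lambda g: _unbroadcast(g * p * a.data ** (p - 1.0), a.data.shape))],
        )

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other**-1.0
        return self * (1.0 / float(other))

    def __rtruediv__(self, other):
        return self**-1.0 * other

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        if a.data.ndim < 2 or b.data.ndim < 2:
            raise ValueError("matmul requires tensors with ndim >= 2")
        return _make(
            a.data @ b.data,
            [
                (a, lambda g: _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)),
                (b, lambda g: _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)),
            ],
        )

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)
        return _make(out_data, [(self, lambda g: g * out_data)])

    def log(self):
        a = self
        return _make(np.log(a.data), [(a, lambda g: g / a.data)])

    def tanh(self):
        out_data = np.tanh(self.data)
        return _make(out_data, [(self, lambda g: g * (1.0 - out_data**2))])

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return _make(out_data, [(self, lambda g: g * out_data * (1.0 - out_data))])

    def relu(self):
        a = self
        return _make(
            np.maximum(a.data, 0.0), [(a, lambda g: g * (a.data > 0.0))]
        )

    def abs(self):
        a = self
        return _make(np.abs(a.data), [(a, lambda g: g * np.sign(a.data))])

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def vjp(g: np.ndarray) -> np.ndarray:
            if axis is None:
                return np.broadcast_to(g, a.data.shape).copy()
            g2 = g
            if not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                for ax in sorted(ax % a.data.ndim for ax in axes):
                    g2 = np.expand_dims(g2, ax)
            return np.broadcast_to(g2, a.data.shape).copy()

        return _make(a.data.sum(axis=axis, keepdims=keepdims), [(a, vjp)])

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / count

    def max(self, axis: int, keepdims: bool = False):
        a = self
        ax = axis % a.data.ndim
        out_data = a.data.max(axis=ax, keepdims=keepdims)
        idx = a.data.argmax(axis=ax)  # first maximum: deterministic tie-break

        def vjp(g: np.ndarray) -> np.ndarray:
            g2 = g if keepdims else np.expand_dims(g, ax)
            mask = np.zeros_like(a.data)
            np.put_along_axis(mask, np.expand_dims(idx, ax), 1.0, axis=ax)
            return mask * np.broadcast_to(g2, a.data.shape)

        return _make(out_data, [(a, vjp)])

    # ---------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return _make(
            a.data.reshape(shape), [(a, lambda g: g.reshape(a.data.shape))]
        )

    def expand_dims(self, axis: int):
        a = self
        return _make(
            np.expand_dims(a.data, axis),
            [(a, lambda g: g.reshape(a.data.shape))],
        )

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return _make(
            np.swapaxes(a.data, ax1, ax2), [(a, lambda g: np.swapaxes(g, ax1, ax2))]
        )

    def __getitem__(self, idx):
        a = self

        def vjp(g: np.ndarray) -> np.ndarray:
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return out

        return _make(a.data[idx], [(a, vjp)])


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i: int):
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return _make(data, [(t, make_vjp(i)) for i, t in enumerate(tensors)])


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    return concat([t.expand_dims(axis) for t in tensors], axis=axis)


def softmax_lastdim(x: Tensor) -> Tensor:
    """Row-softmax over the last axis (max-shifted for stability).

    The shift is a constant: the softmax value is unchanged and the exact
    gradient is preserved.
    """
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


def log_softmax_lastdim(x: Tensor) -> Tensor:
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    s = x - shift
    return s - s.exp().sum(axis=-1, keepdims=True).log()
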