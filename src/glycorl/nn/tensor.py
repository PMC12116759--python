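"""Minimal reverse-mode automatic differentiation on numpy arrays.

A vectorized scalar-output autodiff: `Tensor` wraps an ndarray and records the
operations that produced it; `backward()` on a scalar loss accumulates
gradients into every reachable tensor with ``requires_grad=True``. Only the
operations needed by the dosing agent and the fitted-Q evaluator are
implemented (affine maps, elementwise nonlinearities, reductions, reshaping,
row-repetition and concatenation), each with full numpy broadcasting support.

All arithmetic is float64 for reproducibility of gradient checks.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "concat", "where"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (e.g., target networks)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to `shape`."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple = ()
        self.requires_grad = bool(requires_grad)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"], backward) -> "Tensor":
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            if node._parents == () and node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data + b.data

        def bw(g):
            return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

        return Tensor._make(out_data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: ((a, -g),))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data * b.data

        def bw(g):
            return (
                (a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape)),
            )

        return Tensor._make(out_data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data / b.data

        def bw(g):
            return (
                (a, _unbroadcast(g / b.data, a.data.shape)),
                (b, _unbroadcast(-g * a.data / b.data**2, b.data.shape)),
            )

        return Tensor._make(out_data, (a, b), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data**exponent

        def bw(g):
            return ((a, g * exponent * a.data ** (exponent - 1)),)

        return Tensor._make(out_data, (a,), bw)

    def matmul(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data @ b.data

        def bw(g):
            return ((a, g @ b.data.T), (b, a.data.T @ g))

        return Tensor._make(out_data, (a, b), bw)

    __matmul__ = matmul

    # ---------------------------------------------------------- nonlinearity
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * out_data),))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: ((a, g / a.data),))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * (1.0 - out_data**2)),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: ((a, g * mask),))

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return Tensor._make(np.abs(a.data), (a,), lambda g: ((a, g * sign),))

    def cos(self):
        a = self
        return Tensor._make(np.cos(a.data), (a,), lambda g: ((a, -g * np.sin(a.data)),))

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is None:
                return ((a, np.broadcast_to(g, a.data.shape).copy()),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return ((a, np.broadcast_to(g, a.data.shape).copy()),)

        return Tensor._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int, keepdims: bool = False):
        """Numerically stable log-sum-exp along one axis."""
        axis = axis % self.ndim
        shift = np.max(self.data, axis=axis, keepdims=True)
        shifted = self - Tensor(shift)  # constant shift: gradient-correct
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(shift)
        if not keepdims:
            out = out.reshape(tuple(s for i, s in enumerate(self.shape) if i != axis))
        return out

    # ---------------------------------------------------------------- shaping
    def reshape(self, shape):
        a = self
        orig = a.data.shape
        return Tensor._make(a.data.reshape(shape), (a,), lambda g: ((a, g.reshape(orig)),))

    def repeat_rows(self, n: int):
        """Repeat each row n times along axis 0: (B, ...) -> (B*n, ...)."""
        a = self
        out_data = np.repeat(a.data, n, axis=0)
        orig = a.data.shape

        def bw(g):
            return ((a, g.reshape((orig[0], n) + orig[1:]).sum(axis=1)),)

        return Tensor._make(out_data, (a,), bw)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return ((a, full),)

        return Tensor._make(out_data, (a,), bw)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, pieces))

    return Tensor._make(out_data, tuple(tensors), bw)


def where(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Elementwise select with a constant boolean mask."""
    a, b = _as_tensor(a), _as_tensor(b)
    mask = np.asarray(mask, dtype=bool)
    out_data = np.where(mask, a.data, b.data)

    def bw(g):
        return (
            (a, _unbroadcast(g * mask, a.data.shape)),
            (b, _unbroadcast(g * (~mask), b.data.shape)),
        )

    return Tensor._make(out_data, (a, b), bw)
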