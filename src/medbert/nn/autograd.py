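"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` accumulates gradients by reverse topological
traversal.  Only the primitives needed by the encoder, its heads and the
training loops are implemented — dense algebra via (batched) ``matmul``,
elementwise arithmetic and nonlinearities, reductions with broadcasting-aware
gradient accumulation, integer-index gather for embedding lookup, slicing and
concatenation.  Everything runs in float64: at desk scale the clarity and
testability of exact-ish gradients outweigh speed.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from 1
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core --------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other, fwd, bwd_a, bwd_b) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(fwd(self.data, other.data))
        out.requires_grad = self.requires_grad or other.requires_grad
        if out.requires_grad:
            out._prev = (self, other)

            def _backward(g: np.ndarray) -> None:
                if self.requires_grad or self._prev:
                    self._accum(_unbroadcast(bwd_a(g, self.data, other.data), self.shape))
                if other.requires_grad or other._prev:
                    other._accum(_unbroadcast(bwd_b(g, self.data, other.data), other.shape))

            out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, np.add, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, np.multiply, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other,
            np.divide,
            lambda g, a, b: g / b,
            lambda g, a, b: -g * a / (b * b),
        )

    def __rtruediv__(self, other):
        return Tensor._lift(other).__truediv__(self)

    def __neg__(self):
        return self * (-1.0)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(np.matmul(self.data, other.data))
        out.requires_grad = self.requires_grad or other.requires_grad
        if out.requires_grad:
            out._prev = (self, other)
            a, b = self, other

            def _backward(g: np.ndarray) -> None:
                if a.ndim == 1 and b.ndim == 1:
                    a._accum(g * b.data)
                    b._accum(g * a.data)
                    return
                ad = a.data if a.ndim > 1 else a.data[None, :]
                bd = b.data if b.ndim > 1 else b.data[:, None]
                gg = g
                if a.ndim == 1:
                    gg = np.expand_dims(g, -2)
                if b.ndim == 1:
                    gg = np.expand_dims(gg, -1)
                ga = np.matmul(gg, np.swapaxes(bd, -1, -2))
                gb = np.matmul(np.swapaxes(ad, -1, -2), gg)
                if a.ndim == 1:
                    ga = np.squeeze(ga, -2)
                if b.ndim == 1:
                    gb = np.squeeze(gb, -1)
                a._accum(_unbroadcast(ga, a.shape))
                b._accum(_unbroadcast(gb, b.shape))

            out._backward = _backward
        return out

    def _unary(self, fwd_val: np.ndarray, dfn) -> "Tensor":
        out = Tensor(fwd_val)
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._prev = (self,)

            def _backward(g: np.ndarray) -> None:
                self._accum(dfn(g, fwd_val))

            out._backward = _backward
        return out

    def exp(self):
        return self._unary(np.exp(self.data), lambda g, y: g * y)

    def log(self):
        x = self.data
        return self._unary(np.log(x), lambda g, y: g / x)

    def tanh(self):
        return self._unary(np.tanh(self.data), lambda g, y: g * (1.0 - y * y))

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(y, lambda g, yy: g * yy * (1.0 - yy))

    def relu(self):
        return self._unary(np.maximum(self.data, 0.0), lambda g, y: g * (y > 0))

    def gelu(self):
        """Gaussian error linear unit (tanh approximation, the BERT recipe)."""
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        y = 0.5 * x * (1.0 + t)
        dinner = c * (1.0 + 3 * 0.044715 * x**2)
        dy = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
        return self._unary(y, lambda g, yy: g * dy)

    def softplus(self):
        """log(1 + exp(x)) computed stably; derivative is the sigmoid."""
        x = self.data
        return self._unary(np.logaddexp(0.0, x), lambda g, y: g / (1.0 + np.exp(-x)))

    def sqrt(self):
        y = np.sqrt(self.data)
        return self._unary(y, lambda g, yy: g * 0.5 / yy)

    def pow(self, p: float):
        x = self.data
        return self._unary(x**p, lambda g, y: g * p * x ** (p - 1))

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._prev = (self,)
            shape = self.shape

            def _backward(g: np.ndarray) -> None:
                gg = g
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    for ax in sorted(a % len(shape) for a in axes):
                        gg = np.expand_dims(gg, ax)
                self._accum(np.broadcast_to(gg, shape).copy())

            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._prev = (self,)
            orig = self.shape

            def _backward(g: np.ndarray) -> None:
                self._accum(g.reshape(orig))

            out._backward = _backward
        return out

    def swapaxes(self, a1: int, a2: int):
        out = Tensor(np.swapaxes(self.data, a1, a2))
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._prev = (self,)

            def _backward(g: np.ndarray) -> None:
                self._accum(np.swapaxes(g, a1, a2))

            out._backward = _backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._prev = (self,)
            shape = self.shape

            def _backward(g: np.ndarray) -> None:
                full = np.zeros(shape)
                np.add.at(full, idx, g)
                self._accum(full)

            out._backward = _backward
        return out


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def take(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``table[idx]`` for integer index arrays (embedding lookup)."""
    idx = np.asarray(idx)
    out = Tensor(table.data[idx])
    out.requires_grad = table.requires_grad
    if out.requires_grad:
        out._prev = (table,)

        def _backward(g: np.ndarray) -> None:
            full = np.zeros_like(table.data)
            np.add.at(full, idx.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            table._accum(full)

        out._backward = _backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]

        def _backward(g: np.ndarray) -> None:
            splits = np.cumsum(sizes)[:-1]
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._prev:
                    t._accum(piece)

        out._backward = _backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)

        def _backward(g: np.ndarray) -> None:
            for t, piece in zip(tensors, np.moveaxis(g, axis, 0)):
                if t.requires_grad or t._prev:
                    t._accum(piece)

        out._backward = _backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from primitives (max is detached)."""
    shifted = x - x.data.max(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-12) -> Tensor:
    """Layer normalization over the last axis with learned gain and bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gain + bias


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.data.max(axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


__all__ = [
    "Tensor",
    "take",
    "concat",
    "stack",
    "softmax",
    "log_softmax",
    "layer_norm",
]
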