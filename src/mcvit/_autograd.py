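"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the transformer stack needs: broadcasting
arithmetic, batched matmul, reshape/transpose/slicing/concatenation, padding
and cyclic rolls (window shifting), and the stable nonlinearities
(softmax, sigmoid, GELU, logsumexp). Everything is float64; gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, expit

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

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
    """Reduce ``grad`` back to ``shape`` by summing broadcast dimensions."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- op constructor ---------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: tuple, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._op(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._op(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._op(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bw(g, a=self, e=exponent):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        return Tensor._op(self.data ** exponent, (self,), bw)

    # -- matmul -----------------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._op(np.matmul(self.data, other.data), (self, other), bw)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g, a=self, old=old):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._op(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g, a=self, inv=tuple(inv)):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._op(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._op(self.data[idx], (self,), bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return Tensor._op(out_data, (self,), bw)

    def log(self):
        def bw(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._op(np.log(self.data), (self,), bw)

    def sigmoid(self):
        s = expit(self.data)

        def bw(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._op(s, (self,), bw)

    def gelu(self):
        """Exact GELU: x * Phi(x) with the Gaussian CDF."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / _SQRT2))
        out_data = x * phi

        def bw(g, a=self, phi=phi):
            if a.requires_grad:
                x = a.data
                a._accum(g * (phi + x * np.exp(-0.5 * x * x) * _INV_SQRT_2PI))

        return Tensor._op(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g, a=self, s=s, axis=axis):
            if a.requires_grad:
                a._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        return Tensor._op(s, (self,), bw)

    def logsumexp(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        se = e.sum(axis=axis, keepdims=True)
        out_data = np.squeeze(m + np.log(se), axis=axis)

        def bw(g, a=self, e=e, se=se, axis=axis):
            if a.requires_grad:
                a._accum(np.expand_dims(g, axis) * e / se)

        return Tensor._op(out_data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g, parts=tuple(tensors), splits=tuple(splits), axis=axis):
        pieces = np.split(g, splits, axis=axis)
        for p, piece in zip(parts, pieces):
            if p.requires_grad:
                p._accum(piece)

    return Tensor._op(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def stack(tensors, axis: int = 0) -> Tensor:
    return concatenate([t.reshape(*_insert(t.shape, axis)) for t in tensors], axis=axis)


def _insert(shape, axis):
    shape = list(shape)
    if axis < 0:
        axis += len(shape) + 1
    shape.insert(axis, 1)
    return tuple(shape)


def pad2d(t: Tensor, pad: int) -> Tensor:
    """Zero-pad the two middle axes of a (B, h, w, c) tensor by ``pad``."""
    width = ((0, 0), (pad, pad), (pad, pad), (0, 0))

    def bw(g, a=t, pad=pad):
        if a.requires_grad:
            a._accum(g[:, pad:-pad or None, pad:-pad or None, :])

    return Tensor._op(np.pad(t.data, width), (t,), bw)


def roll2d(t: Tensor, shift: tuple[int, int]) -> Tensor:
    """Cyclic roll over the (h, w) axes of a (B, h, w, c) tensor."""

    def bw(g, a=t, shift=shift):
        if a.requires_grad:
            a._accum(np.roll(g, (-shift[0], -shift[1]), axis=(1, 2)))

    return Tensor._op(np.roll(t.data, shift, axis=(1, 2)), (t,), bw)
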