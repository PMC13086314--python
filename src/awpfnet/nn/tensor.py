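"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations
applied to it in a DAG; calling :meth:`Tensor.backward` on a scalar
result accumulates gradients into every tensor created with
``requires_grad=True`` (and every intermediate node, which is what makes
gradient-based feature attribution possible without hooks).

Only the primitives the network needs are implemented.  Convolution and
pooling live in :mod:`awpfnet.nn.conv`; this module holds the pointwise,
linear-algebra and shape ops.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

DEFAULT_DTYPE = np.float32


def _as_array(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype != DEFAULT_DTYPE:
        arr = arr.astype(DEFAULT_DTYPE)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        else:
            out._parents = ()
            out._backward = None
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None or grad.dtype != DEFAULT_DTYPE else grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- properties --------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, exponent: float):
        data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        data = np.matmul(self.data, other.data)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accum(_unbroadcast(ga, self.data.shape))
            other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __matmul__ = matmul

    # -- pointwise nonlinearities -----------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        data = np.where(mask, self.data, 0)

        def backward(g):
            self._accum(np.where(mask, g, 0))

        return Tensor._make(data, (self,), backward)

    def gelu(self) -> "Tensor":
        # tanh approximation; smooth enough that its own derivative is used
        c = DEFAULT_DTYPE(math.sqrt(2.0 / math.pi))
        a = DEFAULT_DTYPE(0.044715)
        x = self.data
        x2 = x * x
        t = np.tanh(c * (x + a * (x2 * x)))
        data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + DEFAULT_DTYPE(3.0) * a * x2)
            dt = (1.0 - t * t) * dinner
            self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return Tensor._make(data, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).astype(DEFAULT_DTYPE))

        return Tensor._make(_as_array(data), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = 1
            for a in axes:
                n *= self.data.shape[a]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._make(data, (self,), backward)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        data = self.data.transpose(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(data, (self,), backward)

    def pad2d(self, pad_h: int, pad_w: int) -> "Tensor":
        """Zero-pad the bottom/right of the last two axes."""
        if pad_h == 0 and pad_w == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(0, pad_h), (0, pad_w)]
        data = np.pad(self.data, width)
        H, W = self.data.shape[-2:]

        def backward(g):
            self._accum(g[..., :H, :W])

        return Tensor._make(data, (self,), backward)

    def crop2d(self, h: int, w: int) -> "Tensor":
        """Keep the top-left h x w of the last two axes."""
        if (h, w) == self.data.shape[-2:]:
            return self
        data = np.ascontiguousarray(self.data[..., :h, :w])
        shape = self.data.shape

        def backward(g):
            full = np.zeros(shape, dtype=DEFAULT_DTYPE)
            full[..., :h, :w] = g
            self._accum(full)

        return Tensor._make(data, (self,), backward)

    def roll2d(self, shift_h: int, shift_w: int) -> "Tensor":
        """Cyclic roll of the last two axes."""
        if shift_h == 0 and shift_w == 0:
            return self
        data = np.roll(self.data, (shift_h, shift_w), axis=(-2, -1))

        def backward(g):
            self._accum(np.roll(g, (-shift_h, -shift_w), axis=(-2, -1)))

        return Tensor._make(data, (self,), backward)

    # -- softmax -----------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = (e / e.sum(axis=axis, keepdims=True)).astype(DEFAULT_DTYPE)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        return Tensor._make(s, (self,), backward)


# -- free functions --------------------------------------------------------


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """``x @ weight.T + bias`` with weight of shape (out, in)."""
    data = x.data @ weight.data.T
    if bias is not None:
        data = data + bias.data

    def backward(g):
        x._accum(_unbroadcast(g @ weight.data, x.data.shape))
        gw = np.swapaxes(g, -1, -2) @ x.data
        while gw.ndim > 2:
            gw = gw.sum(axis=0)
        weight._accum(gw)
        if bias is not None:
            gb = g
            while gb.ndim > 1:
                gb = gb.sum(axis=0)
            bias._accum(gb)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(data, parents, backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of integer labels."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accum((float(g) / n) * p)

    return Tensor._make(_as_array(loss), (logits,), backward)


def add_constant(x: Tensor, const: np.ndarray) -> Tensor:
    """Add a non-learnable array (e.g. an attention mask) to ``x``."""
    data = x.data + const

    def backward(g):
        x._accum(_unbroadcast(g, x.data.shape))

    return Tensor._make(data, (x,), backward)


def take_rows(table: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows of a 2-D table by an integer index array.

    Output shape is ``index.shape + (table.shape[1],)``; used for the
    relative-position bias lookup.
    """
    data = table.data[index]

    def backward(g):
        grad = np.zeros_like(table.data)
        np.add.at(grad, index.ravel(), g.reshape(-1, table.data.shape[1]))
        table._accum(grad)

    return Tensor._make(data, (table,), backward)


def stack_tensors(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._make(data, tuple(tensors), backward)
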