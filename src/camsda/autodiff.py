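"""Minimal reverse-mode automatic differentiation over numpy arrays.

The adaptation losses (joint-label cross-entropy, reweighted moment
distances, per-domain classification) all need gradients with respect to
the shared feature extractor and the heads.  The networks involved are
small (two-layer perceptrons, a compact convolutional net), so a compact
tape suffices: each :class:`Tensor` wraps a float64 ndarray, records its
parents and a closure that routes the upstream gradient to them, and
``backward`` replays the tape in reverse topological order.

Only the primitives the package actually uses are implemented.  Gradient
correctness is pinned by central finite-difference tests.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
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
    """A node in the computation graph: value, gradient slot, parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents: Sequence[Tensor] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # -- graph plumbing ------------------------------------------------
    @classmethod
    def _op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> np.ndarray:
        return self.data

    # -- shape views ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __float__(self):
        return float(self.data)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor._op(self.data @ other.data, (self, other), backward)

    def square(self):
        def backward(g):
            self._accumulate(2.0 * self.data * g)

        return Tensor._op(self.data**2, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._op(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._op(self.data * mask, (self,), backward)

    def clip_min(self, floor: float):
        """Lower clip; gradient passes only through unclipped entries."""
        mask = self.data >= floor

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._op(np.maximum(self.data, floor), (self,), backward)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def norm2(self):
        """Euclidean norm of the flattened tensor, with subgradient 0 at 0."""
        value = float(np.sqrt((self.data**2).sum()))

        def backward(g):
            if value > 0.0:
                self._accumulate(g * self.data / value)
            else:  # at exactly zero the subgradient 0 is used
                self._accumulate(np.zeros_like(self.data))

        return Tensor._op(value, (self,), backward)

    # -- row selection / softmax ---------------------------------------
    def gather_rows(self, index):
        """out[i] = self[i, index[i]] for a 2-D tensor."""
        index = np.asarray(index, dtype=np.intp)
        rows = np.arange(self.data.shape[0])

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (rows, index), g)
            self._accumulate(full)

        return Tensor._op(self.data[rows, index], (self,), backward)

    def take_rows(self, index):
        """Select rows of a 2-D tensor (differentiable slice)."""
        index = np.asarray(index, dtype=np.intp)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            self._accumulate(full)

        return Tensor._op(self.data[index], (self,), backward)

    def softmax(self):
        """Row-wise softmax of a 2-D tensor (max-shifted for stability)."""
        shift = Tensor(self.data.max(axis=1, keepdims=True))  # constant shift
        e = (self - shift).exp()
        return e * reciprocal(e.sum(axis=1, keepdims=True))

    # -- convolution / pooling -----------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1):
        """Valid 2-D convolution; input (n, c_in, h, w), weight (c_out, c_in, kh, kw)."""
        x, w = self.data, weight.data
        kh, kw = w.shape[2], w.shape[3]
        windows = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        out = np.einsum("ncxykl,ockl->noxy", windows, w, optimize=True)
        out += bias.data[None, :, None, None]
        oh, ow = out.shape[2], out.shape[3]

        def backward(g):
            weight._accumulate(np.einsum("ncxykl,noxy->ockl", windows, g, optimize=True))
            bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dx = np.zeros_like(x)
                for i in range(kh):
                    for j in range(kw):
                        contrib = np.einsum("noxy,oc->ncxy", g, w[:, :, i, j], optimize=True)
                        dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += contrib
                self._accumulate(dx)

        return Tensor._op(out, (self, weight, bias), backward)

    def global_avg_pool(self):
        """Mean over the two spatial axes of an (n, c, h, w) tensor."""
        return self.mean(axis=(2, 3))


def reciprocal(t: Tensor) -> Tensor:
    out_data = 1.0 / t.data

    def backward(g):
        t._accumulate(-g * out_data**2)

    return Tensor._op(out_data, (t,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
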