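"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it.  Calling :meth:`Tensor.backward` on a scalar result walks the recorded
graph in reverse topological order and accumulates gradients into ``.grad``
on every node, so gradients of intermediate feature maps (needed e.g. for
class-activation maps) are available without extra bookkeeping.

Only the operations the segmentation networks need are implemented; each op
provides a fused vector-Jacobian product rather than being composed from
smaller primitives, keeping graphs short and Python overhead low.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
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

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.shape}, dtype={self.dtype}{flag})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph mechanics ---------------------------------------------------
    def _needs_graph(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (27-block stages)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other, self.dtype)
        out_data = self.data + other.data

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        if not self._needs_graph(other):
            return Tensor(out_data)
        return Tensor(out_data, True, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out_data = -self.data

        def bw(g):
            self._accumulate(-g)

        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other, self.dtype)
        out_data = self.data * other.data

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        if not self._needs_graph(other):
            return Tensor(out_data)
        return Tensor(out_data, True, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other, self.dtype)
        out_data = self.data / other.data

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        if not self._needs_graph(other):
            return Tensor(out_data)
        return Tensor(out_data, True, (self, other), bw)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other, self.dtype) / self

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), bw)

    # -- transcendental ----------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), bw)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bw(g):
            self._accumulate(g / self.data)

        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), bw)

    def sqrt(self) -> "Tensor":
        return self**0.5

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(a % self.ndim for a in axes))
            self._accumulate(np.broadcast_to(g, self.shape))

        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accumulate(g.reshape(self.shape))

        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), bw)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            self._accumulate(g.transpose(inverse))

        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), bw)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), bw)

    # -- linear algebra ----------------------------------------------------
    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other, self.dtype)
        out_data = self.data @ other.data

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        if not self._needs_graph(other):
            return Tensor(out_data)
        return Tensor(out_data, True, (self, other), bw)


class Parameter(Tensor):
    """A trainable tensor (leaf node of the graph)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    elif dtype is not None and arr.dtype.kind in "iub":
        arr = arr.astype(dtype)
    return Tensor(arr)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(np.asarray(t)) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    if not any(t.requires_grad for t in tensors):
        return Tensor(out_data)
    return Tensor(out_data, True, tuple(tensors), bw)
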