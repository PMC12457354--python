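"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it on a tape; :meth:`Tensor.backward` replays the tape in reverse
topological order and accumulates gradients.  Only the operations needed by
the NER stack (affine maps, gated recurrences, attention, log-space dynamic
programs) are provided.  Broadcasting follows numpy semantics; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import contextlib
from typing import Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the block (inference / evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph plumbing ------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient on non-scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: tapes from long sequences overflow recursion
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
        self.grad = grad.astype(np.float32, copy=False)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(ga)
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(gb)

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def swapaxes(self, a: int, b: int):
        def bwd(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), bwd)

    def __getitem__(self, idx):
        parts = idx if isinstance(idx, tuple) else (idx,)
        advanced = any(isinstance(p, (np.ndarray, list)) for p in parts)

        def bwd(g):
            full = np.zeros_like(self.data)
            if advanced:
                np.add.at(full, idx, g)  # scatter-add handles repeated indices
            else:
                full[idx] += g
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(ge, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)


# -- free functions ----------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]

    def bwd(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accum(gp)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bwd)


def unstack(x: Tensor, axis: int = 0) -> list[Tensor]:
    """Split `x` into views along `axis` (inverse of :func:`stack`)."""
    n = x.data.shape[axis]
    moved = np.moveaxis(x.data, axis, 0)
    outs = []
    for i in range(n):
        def bwd(g, i=i):
            full = np.zeros_like(x.data)
            np.moveaxis(full, axis, 0)[i] = g
            x._accum(full)

        outs.append(Tensor._make(moved[i], (x,), bwd))
    return outs


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accum(out_data * (g - dot))

    return Tensor._make(out_data, (x,), bwd)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out_data = (np.log(s) + m)
    soft = e / s  # softmax along axis, reused for the gradient

    def bwd(g):
        ge = g if keepdims else np.expand_dims(g, axis)
        x._accum(ge * soft)

    return Tensor._make(out_data if keepdims else out_data.squeeze(axis), (x,), bwd)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup `weight[ids]` with scatter-add gradient into the table."""
    ids = np.asarray(ids)
    if ids.size and (ids.min() < 0 or ids.max() >= weight.data.shape[0]):
        raise IndexError(
            f"embedding id out of range [0, {weight.data.shape[0]}): "
            f"min={ids.min()}, max={ids.max()}"
        )

    def bwd(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, weight.data.shape[1]))
        weight._accum(full)

    return Tensor._make(weight.data[ids], (weight,), bwd)


def where(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Elementwise select; `mask` is a constant boolean array."""
    a, b = Tensor._coerce(a), Tensor._coerce(b)

    def bwd(g):
        if a.requires_grad:
            a._accum(np.where(mask, g, 0.0))
        if b.requires_grad:
            b._accum(np.where(mask, 0.0, g))

    return Tensor._make(np.where(mask, a.data, b.data), (a, b), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    return x * Tensor(keep)


def parameter(data, name: str | None = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True, name=name)


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out)).astype(np.float32)
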