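"""Tape-based reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ndarray plus the local vector-Jacobian
products linking it to its parents. ``Tensor.backward()`` topologically
sorts the tape and accumulates gradients into every tensor created
with ``requires_grad=True``. Broadcasting follows NumPy rules; the
gradient of a broadcast operand is summed back to its original shape.

Only the primitives the package's models need are implemented:
elementwise arithmetic, abs/relu/tanh/sigmoid/exp/log/softplus, 2-D
matmul, reductions, reshape/transpose/concat/stack, integer gather
(``take``) and a numerically stable logsumexp.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import special as spsp

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over dims that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_pv")
    __array_priority__ = 100

    def __init__(self, data, requires_grad: bool = False,
                 _pv: Sequence[tuple["Tensor", Callable]] = ()):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in _pv)
        self.grad: np.ndarray | None = None
        self._pv = tuple(_pv)

    # -- infrastructure ------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p, _ in node._pv:
                if p.requires_grad and id(p) not in seen:
                    stack_.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._pv:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, vjp in node._pv:
                if not p.requires_grad:
                    continue
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                elif not p._pv:
                    p.grad = pg if p.grad is None else p.grad + pg
                else:
                    grads[id(p)] = pg
        # leaves reached directly (self is leaf)
        if not self._pv and self.grad is None:
            self.grad = np.ones_like(self.data)

    # -- arithmetic ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = self.data + other.data
        return Tensor(out, _pv=(
            (self, lambda g: _unbroadcast(g, self.shape)),
            (other, lambda g: _unbroadcast(g, other.shape)),
        ))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _pv=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self.data * other.data
        return Tensor(out, _pv=(
            (self, lambda g: _unbroadcast(g * other.data, self.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.shape)),
        ))

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        out = self.data @ other.data
        return Tensor(out, _pv=(
            (self, lambda g: g @ other.data.T),
            (other, lambda g: self.data.T @ g),
        ))

    # -- elementwise nonlinearities -------------------------------------

    def abs(self):
        sign = np.sign(self.data)  # subgradient 0 at 0
        return Tensor(np.abs(self.data), _pv=((self, lambda g: g * sign),))

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, _pv=((self, lambda g: g * mask),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, _pv=((self, lambda g: g * (1.0 - out**2)),))

    def sigmoid(self):
        out = spsp.expit(self.data)
        return Tensor(out, _pv=((self, lambda g: g * out * (1.0 - out)),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, _pv=((self, lambda g: g * out),))

    def log(self):
        return Tensor(np.log(self.data),
                      _pv=((self, lambda g: g / self.data),))

    def square(self):
        return Tensor(self.data**2, _pv=((self, lambda g: g * 2.0 * self.data),))

    def softplus(self):
        """log(1 + exp(x)), computed stably; derivative sigmoid(x)."""
        out = np.logaddexp(0.0, self.data)
        sig = spsp.expit(self.data)
        return Tensor(out, _pv=((self, lambda g: g * sig),))

    # -- reductions -----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.shape).copy()

        return Tensor(out, _pv=((self, vjp),))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def logsumexp(self, axis: int, keepdims: bool = False):
        out = spsp.logsumexp(self.data, axis=axis, keepdims=keepdims)
        softmax = np.exp(
            self.data - spsp.logsumexp(self.data, axis=axis, keepdims=True))

        def vjp(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            return gg * softmax

        return Tensor(out, _pv=((self, vjp),))

    # -- shape ops ------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(self.data.reshape(shape),
                      _pv=((self, lambda g: g.reshape(old)),))

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes),
                      _pv=((self, lambda g: g.transpose(inv)),))

    @property
    def T(self):
        return self.transpose()

    def take(self, indices: np.ndarray, axis: int):
        """Integer gather along ``axis``; backward scatter-adds."""
        indices = np.asarray(indices)
        if indices.ndim < 1:
            indices = indices.reshape(1)
        out = np.take(self.data, indices, axis=axis)
        nd_idx = indices.ndim

        def vjp(g):
            grad = np.zeros_like(self.data)
            gm = np.moveaxis(grad, axis, 0)
            # out shape = pre + S + post with pre = data.shape[:axis];
            # bring the S index dims to the front to align with gm[idx]
            g2 = np.moveaxis(g, tuple(range(axis, axis + nd_idx)),
                             tuple(range(nd_idx)))
            np.add.at(gm, indices, g2)
            return grad

        return Tensor(out, _pv=((self, vjp),))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(out, _pv=tuple(
        (t, make_vjp(i)) for i, t in enumerate(tensors)))


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def make_vjp(i):
        return lambda g: np.take(g, i, axis=axis)

    return Tensor(out, _pv=tuple(
        (t, make_vjp(i)) for i, t in enumerate(tensors)))
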