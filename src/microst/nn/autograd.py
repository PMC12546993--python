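"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the forecaster: broadcast-aware elementwise
arithmetic, matmul, a two-operand einsum, the usual saturating
non-linearities, concatenation/slicing/padding/reshaping, and reductions.
Gradients are accumulated through a topologically sorted backward sweep.

Deliberately small and fully deterministic — every result is a plain
float64 numpy computation, so identical seeds give bit-identical training
runs on any machine.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "einsum2"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
            gb = _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
            return ga, gb

        return self._make(out_data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(s, (self,), lambda g: (g * s * (1 - s),))

    def tanh(self):
        t = np.tanh(self.data)
        return self._make(t, (self,), lambda g: (g * (1 - t * t),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def abs(self):
        sign = np.sign(self.data)
        return self._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        return self._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, axes):
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(axes),
            (self,),
            lambda g: (g.transpose(inv),),
        )

    def __getitem__(self, key):
        out_data = self.data[key]
        shape = self.shape

        def backward(g):
            full = np.zeros(shape)
            np.add.at(full, key, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    def pad_last(self, left: int, right: int = 0):
        """Zero-pad the final axis (used for causal convolution)."""
        pads = [(0, 0)] * (self.ndim - 1) + [(left, right)]
        out_data = np.pad(self.data, pads)
        t = self.shape[-1]

        def backward(g):
            sl = [slice(None)] * (self.ndim - 1) + [slice(left, left + t)]
            return (g[tuple(sl)],)

        return self._make(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None):
        out_data = self.data.sum(axis=axis)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g_exp = np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad
                else:
                    parent.grad = parent.grad + pgrad

    def zero_grad(self):
        self.grad = None


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    """Concatenate tensors along an axis, splitting the gradient back."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def einsum2(eq: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with autodiff.

    Requires explicit subscripts without ellipses or repeated indices
    within one operand; every input index must appear in the output or in
    the other operand (true for all contractions used by the model).
    """
    lhs, out_sub = eq.split("->")
    a_sub, b_sub = lhs.split(",")
    a = Tensor._lift(a)
    b = Tensor._lift(b)
    out_data = np.einsum(eq, a.data, b.data)

    def backward(g):
        ga = np.einsum(f"{out_sub},{b_sub}->{a_sub}", g, b.data)
        gb = np.einsum(f"{a_sub},{out_sub}->{b_sub}", a.data, g)
        return ga, gb

    out = Tensor(out_data)
    if a.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = (a, b)
        out._backward = backward
    return out
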