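"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape: just the operations the recurrent graph model
needs (broadcasting arithmetic, batched matmul, ReLU/tanh/logistic, axis
reductions, concatenation, softmax/log-softmax, and a batched row gather with
scatter-add backward). Gradients are only propagated into branches that
contain a parameter, so large constant inputs (edge tensors) cost nothing
extra on the backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        """Accumulate gradients of this (typically scalar) tensor's output."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                current, it = stack[-1]
                advanced = False
                for parent in it:
                    if parent.requires_grad and id(parent) not in seen:
                        seen.add(id(parent))
                        stack.append((parent, iter(parent._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(current)
                    stack.pop()

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.data.shape)
                )

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def tanh(self):
        out = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out ** 2))

        return Tensor(out, parents=(self,), backward=bwd)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=bwd)

    def log(self, eps: float = 1e-12):
        clipped = np.clip(self.data, eps, None)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / clipped)

        return Tensor(np.log(clipped), parents=(self,), backward=bwd)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, 1.0) * g)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims=False):
        idx = np.argmax(self.data, axis=axis)
        out = np.max(self.data, axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            gg = g if not keepdims else np.squeeze(g, axis=axis)
            np.put_along_axis(
                full, np.expand_dims(idx, axis), np.expand_dims(gg, axis), axis=axis
            )
            self._accumulate(full)

        return Tensor(out, parents=(self,), backward=bwd)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def gather_rows(self, index: np.ndarray):
        """Batched row gather: self (B, n, H), index (B, k) -> (B, k, H)."""
        index = np.asarray(index)
        idx3 = index[..., None]
        out = np.take_along_axis(self.data, np.broadcast_to(
            idx3, index.shape + (self.data.shape[-1],)), axis=-2)

        def bwd(g):
            if not self.requires_grad:
                return
            # put_along_axis would overwrite duplicate indices; scatter-add instead
            full = np.zeros_like(self.data)
            B = self.data.shape[0]
            for b in range(B):
                np.add.at(full[b], index[b], g[b])
            self._accumulate(full)

        return Tensor(out, parents=(self,), backward=bwd)

    # -- softmax family ---------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                dot = (g * out).sum(axis=axis, keepdims=True)
                self._accumulate(out * (g - dot))

        return Tensor(out, parents=(self,), backward=bwd)

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out = shifted - lse
        soft = np.exp(out)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor(out, parents=(self,), backward=bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bwd)


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack same-shape tensors along a new leading axis."""
    tensors = [Tensor.as_tensor(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(g[i])

    return Tensor(np.stack([t.data for t in tensors]),
                  parents=tuple(tensors), backward=bwd)
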