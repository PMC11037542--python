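"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable parts of this package (hypergraph encoders, projection heads,
attention blocks, matrix-completion decoder) are small dense networks trained
full-batch on desk-scale problems, so a compact tape-based engine is all that
is needed.  A :class:`Tensor` wraps a float64 ndarray; operations on tensors
record closures that propagate gradients back to their parents, and
:meth:`Tensor.backward` runs the tape in reverse topological order.

Only the operations the model uses are implemented.  Everything is
deterministic: no op consults global random state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph holding a float64 array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data.item())

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from this (scalar or array) tensor with seed grad 1."""
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    # ------------------------------------------------------------- shape ops
    @property
    def T(self) -> "Tensor":
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.T)

        return self._make(a.data.T, (a,), backward)

    def reshape(self, *shape) -> "Tensor":
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(ge, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------- element-wise
    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def sigmoid(self) -> "Tensor":
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * s * (1.0 - s))

        return self._make(s, (a,), backward)

    def exp(self) -> "Tensor":
        a = self
        e = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * e)

        return self._make(e, (a,), backward)

    def log(self) -> "Tensor":
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def sqrt(self) -> "Tensor":
        a = self
        r = np.sqrt(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * 0.5 / r)

        return self._make(r, (a,), backward)

    def l2_normalize(self, axis: int = 1, eps: float = 1e-12) -> "Tensor":
        """Row-normalize to unit Euclidean norm; zero rows map to zero rows."""
        sq = (self * self).sum(axis=axis, keepdims=True)
        norm = (sq + eps).sqrt()
        return self / norm


def concat(tensors: list, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, splitting gradients back."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape=None) -> np.ndarray:
    """Glorot/Xavier uniform initialization scaled by fan-in and fan-out."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a name->Tensor parameter mapping.

    Update order follows dict insertion order, so runs are reproducible.
    """

    def __init__(self, params: dict, lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * p.grad
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
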