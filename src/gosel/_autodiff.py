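"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the package's small neural networks need:
broadcast-aware elementwise arithmetic, (batched) matmul, relu/sigmoid/
exp/log/pow, softmax along an axis, reductions, stacking/indexing, and an
Adam optimizer.  Everything is float64; gradients accumulate into
``Tensor.grad`` after calling ``backward()`` on a scalar output.

The engine is deliberately tiny: a tape of (parents, backward-closure)
pairs walked in reverse topological order.  Correctness of the gradients
is established in the test suite by comparison with central finite
differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "relu", "sigmoid", "exp", "log", "softmax", "stack", "clip", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, k: float):
        """Elementwise power with a constant exponent.

        ``d/dx x**k = k x**(k-1)``; at k == 0 the derivative is identically 0,
        which matters for focal exponents set to zero.
        """
        k = float(k)

        def backward(g):
            if self.requires_grad:
                if k == 0.0:
                    self._accum(np.zeros_like(self.data))
                    return
                self._accum(g * k * np.power(self.data, k - 1.0))

        return Tensor._from_op(np.power(self.data, k), (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._from_op(self.data[idx], (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return Tensor._from_op(np.swapaxes(self.data, a, b), (self,), backward)

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver ------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS post-order
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        while visiting:
            node, done = visiting.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    visiting.append((p, False))
        del stack_
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# -- elementwise nonlinearities ---------------------------------------------


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0

    def backward(g):
        if t.requires_grad:
            t._accum(g * mask)

    return Tensor._from_op(np.where(mask, t.data, 0.0), (t,), backward)


def sigmoid(t: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-t.data))

    def backward(g):
        if t.requires_grad:
            t._accum(g * s * (1.0 - s))

    return Tensor._from_op(s, (t,), backward)


def exp(t: Tensor) -> Tensor:
    e = np.exp(t.data)

    def backward(g):
        if t.requires_grad:
            t._accum(g * e)

    return Tensor._from_op(e, (t,), backward)


def log(t: Tensor) -> Tensor:
    def backward(g):
        if t.requires_grad:
            t._accum(g / t.data)

    return Tensor._from_op(np.log(t.data), (t,), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if t.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            t._accum(s * (g - dot))

    return Tensor._from_op(s, (t,), backward)


def clip(t: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside the interval."""
    inside = (t.data > lo) & (t.data < hi)

    def backward(g):
        if t.requires_grad:
            t._accum(g * inside)

    return Tensor._from_op(np.clip(t.data, lo, hi), (t,), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis).reshape(t.shape))

    return Tensor._from_op(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward)


# -- optimizer ----------------------------------------------------------------


class Adam:
    """Adam with optional coupled L2 weight decay.

    Parameters whose gradient is ``None`` after a backward pass are left
    untouched, including their moment estimates — a branch of the model that
    did not participate in the forward pass stays bit-identical.
    """

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = [0] * len(self.params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._t[i] += 1
            t = self._t[i]
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** t)
            vhat = self._v[i] / (1 - self.b2 ** t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
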