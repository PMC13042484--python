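"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operator set the dual-view graph autoencoder needs:
broadcasting arithmetic, matrix products, transpose, relu/tanh/exp/log,
axis reductions, and an Adam optimizer.  Gradients are accumulated by
reverse topological traversal from a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "relu", "tanh", "exp", "log", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # ---- helpers -------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad)

        def _bw(g):
            self._accum(g.T)

        out._backward, out._prev = _bw, (self,)
        return out

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=float), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def _make(self, data, parents, bw) -> "Tensor":
        out = Tensor(data, any(p.requires_grad for p in parents))
        out._backward, out._prev = bw, parents
        return out

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def _bw(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), _bw)

    __radd__ = __add__

    def __neg__(self):
        def _bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), _bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def _bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), _bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def _bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), _bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def _bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), _bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def _bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), _bw)

    # ---- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def _bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), _bw)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / count

    # ---- autodiff driver ----------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                g = t.grad if t.grad is not None else np.zeros_like(t.data)
                t._backward(g)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def _bw(g):
        x._accum(g * mask)

    return x._make(x.data * mask, (x,), _bw)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)

    def _bw(g):
        x._accum(g * (1 - y**2))

    return x._make(y, (x,), _bw)


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)

    def _bw(g):
        x._accum(g * y)

    return x._make(y, (x,), _bw)


def log(x: Tensor) -> Tensor:
    def _bw(g):
        x._accum(g / x.data)

    return x._make(np.log(x.data), (x,), _bw)


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
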