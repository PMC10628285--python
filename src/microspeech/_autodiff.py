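"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the recurrent sequence decoder: dense affine
maps, elementwise gating nonlinearities, column slicing for fused LSTM
gates, and a fused softmax cross-entropy.  Gradients flow through a
dynamically built tape; ``Tensor.backward`` runs the topologically
sorted reverse sweep.  Everything is float64 and single-threaded, so a
fixed seed gives bit-identical training runs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverses numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ---------------------------------------------------

    def _make(self, data, prev, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

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
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- ops --------------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return self._make(self.data + other.data, (self, other), backward)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return self._make(self.data * other.data, (self, other), backward)

    def __matmul__(self, other):
        def backward(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        return self._make(self.data @ other.data, (self, other), backward)

    def cols(self, j0: int, j1: int) -> "Tensor":
        """Column slice [:, j0:j1] (used to split fused LSTM gates)."""

        def backward(g):
            if self.requires_grad:
                self.grad[:, j0:j1] += g

        return self._make(self.data[:, j0:j1], (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self.grad += g * (1.0 - out_data ** 2)

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self.grad += g * out_data * (1.0 - out_data)

        return self._make(out_data, (self,), backward)

    def sum(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self.grad += g * np.ones_like(self.data)

        return self._make(self.data.sum(), (self,), backward)

    def scale(self, a: float) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self.grad += a * g

        return self._make(self.data * a, (self,), backward)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of row-wise softmax against integer targets."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(targets)
    loss = -np.log(probs[np.arange(n), targets] + 1e-300).mean()

    def backward(g):
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(n), targets] -= 1.0
            logits.grad += g * d / n

    out = Tensor(loss)
    out.requires_grad = logits.requires_grad
    if out.requires_grad:
        out._prev = (logits,)
        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.data)
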