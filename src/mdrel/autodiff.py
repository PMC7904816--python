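"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train the hierarchical bi-LSTM: 2-D tensors,
matmul, broadcasting add for biases, elementwise ops, slicing, concat,
embedding gather, and a fused softmax cross-entropy.  Gradients are
accumulated by a topological backward sweep, micrograd-style.  No
broadcasting beyond bias rows is supported; shapes are the caller's
responsibility.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # ------------------------------------------------------------------ ops

    def __matmul__(self, other: "Tensor") -> "Tensor":
        out = _node(self.data @ other.data, (self, other))

        def backward(g):
            if self.requires_grad or self._prev:
                self._accum(g @ other.data.T)
            if other.requires_grad or other._prev:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    def __add__(self, other: "Tensor") -> "Tensor":
        out = _node(self.data + other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            out = _node(self.data * other.data, (self, other))

            def backward(g):
                self._accum(_unbroadcast(g * other.data, self.data.shape))
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        else:  # constant array / scalar
            const = np.asarray(other, dtype=np.float64)
            out = _node(self.data * const, (self,))

            def backward(g):
                self._accum(_unbroadcast(g * const, self.data.shape))

        out._backward = backward
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = _node(t, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -50, 50)))
        out = _node(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        out = _node(self.data[:, start:stop], (self,))

        def backward(g):
            full = np.zeros_like(self.data)
            full[:, start:stop] = g
            self._accum(full)

        out._backward = backward
        return out

    # -------------------------------------------------------------- backward

    def backward(self) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _node(data: np.ndarray, prev: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._prev = tuple(p for p in prev if p.requires_grad or p._prev)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient g down to ``shape`` (bias-row broadcasting only)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        offset = 0
        for t, size in zip(tensors, sizes):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(offset, offset + size)
            t._accum(g[tuple(idx)])
            offset += size

    out._backward = backward
    return out


def gather_rows(table: Tensor, ids: np.ndarray) -> Tensor:
    """Embedding lookup: table [V, d], ids [B] -> [B, d]."""
    out = _node(table.data[ids], (table,))

    def backward(g):
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, ids, g)

    out._backward = backward
    return out


def mean_rows(tensors: list[Tensor]) -> Tensor:
    """Elementwise mean of same-shaped tensors."""
    out = _node(np.mean([t.data for t in tensors], axis=0), tuple(tensors))
    k = float(len(tensors))

    def backward(g):
        for t in tensors:
            t._accum(g / k)

    out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy over the batch; returns (loss, probabilities)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    loss_val = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    out = _node(np.asarray(loss_val), (logits,))

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accum(g * grad / n)

    out._backward = backward
    return out, probs


class Adam:
    """Adam optimiser over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
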