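"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the point-set network needs: dense
layers on the trailing axis, ReLU, concatenation, index gathering,
axis max-pooling, constant-weighted sums, dropout, and log-softmax with
negative log-likelihood. Gradients propagate through a topologically
sorted tape.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward: Optional[Callable] = None,
                 requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ----- operations ------------------------------------------------------

    def linear(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """y = x @ W + b on the trailing axis; x is (..., Cin)."""
        x = self.data
        out = x @ weight.data + bias.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ weight.data.T)
            if weight.requires_grad:
                weight._accumulate(
                    x.reshape(-1, x.shape[-1]).T @ g.reshape(-1, g.shape[-1])
                )
            if bias.requires_grad:
                bias._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))

        return Tensor(out, (self, weight, bias), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(out, (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        out = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    index = [slice(None)] * g.ndim
                    index[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                    t._accumulate(g[tuple(index)])

        return Tensor(out, tuple(tensors), backward)

    def gather(self, index: np.ndarray) -> "Tensor":
        """y = x[index] along axis 0; index may have any shape."""
        index = np.asarray(index)
        out = self.data[index]

        def backward(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, index.reshape(-1),
                          g.reshape(-1, *self.data.shape[1:]))
                self._accumulate(gx)

        return Tensor(out, (self,), backward)

    def max(self, axis: int) -> "Tensor":
        out = self.data.max(axis=axis)
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.put_along_axis(
                    gx, argmax, np.expand_dims(g, axis), axis=axis
                )
                self._accumulate(gx)

        return Tensor(out, (self,), backward)

    def mul_const(self, c) -> "Tensor":
        c = np.asarray(c, dtype=np.float64)
        out = self.data * c

        def backward(g):
            if self.requires_grad:
                grad = g * c
                # reduce broadcast axes back to self's shape
                extra = grad.ndim - self.data.ndim
                if extra > 0:
                    grad = grad.sum(axis=tuple(range(extra)))
                for ax, n in enumerate(self.data.shape):
                    if n == 1 and grad.shape[ax] != 1:
                        grad = grad.sum(axis=ax, keepdims=True)
                self._accumulate(grad)

        return Tensor(out, (self,), backward)

    def sum(self, axis: int) -> "Tensor":
        out = self.data.sum(axis=axis)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.expand_dims(g, axis)
                                 * np.ones_like(self.data))

        return Tensor(out, (self,), backward)

    def dropout(self, p: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; call only in training mode."""
        keep = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return self.mul_const(keep)

    def log_softmax(self) -> "Tensor":
        x = self.data
        shifted = x - x.max(axis=-1, keepdims=True)
        logz = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
        out = shifted - logz
        softmax = np.exp(out)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g - softmax * g.sum(axis=-1, keepdims=True))

        return Tensor(out, (self,), backward)

    def nll_loss(self, labels: np.ndarray) -> "Tensor":
        """Mean negative log-likelihood of rows of log-probabilities."""
        labels = np.asarray(labels, dtype=np.int64)
        n = self.data.shape[0]
        picked = self.data[np.arange(n), labels]
        out = -picked.mean()

        def backward(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                gx[np.arange(n), labels] = -g / n
                self._accumulate(gx)

        return Tensor(out, (self,), backward)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None
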