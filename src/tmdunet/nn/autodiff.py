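"""Reverse-mode automatic differentiation on NCHW arrays.

A small define-by-run tape: every operation returns a :class:`Tensor` that
remembers its parents and a closure accumulating gradients into them.
Convolutions run through an im2col/GEMM path; all arithmetic is float32.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """An array plus the bookkeeping needed to backpropagate through it."""

    __slots__ = ("data", "grad", "_backward", "_parents")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, seed):
        """Backpropagate ``dL/dself = seed`` through the tape."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.accumulate(np.asarray(seed, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data)

    @property
    def size(self):
        return self.data.size
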