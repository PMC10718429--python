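"""Minimal reverse-mode autodiff over NumPy arrays.

Just enough machinery for encoder-decoder segmentation networks: a
:class:`Var` node wrapping an ``ndarray`` records its parents and a closure
that accumulates gradients into them; :meth:`Var.backward` runs a topological
sweep. All ops used by the architectures live in :mod:`sharpseg.nn.ops`.

Arrays are kept in ``float32``; gradients accumulate in the same dtype.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Var:
    """A differentiable array node.

    ``trainable`` marks leaf parameters whose ``grad`` the optimizer reads;
    non-leaf nodes free their gradient buffers after the backward sweep.
    """

    __slots__ = ("data", "grad", "_parents", "_backward", "trainable")

    def __init__(self, data, parents=(), backward=None, trainable=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.trainable = trainable

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=DTYPE).copy()
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, seed=None):
        """Reverse sweep from this node; ``seed`` defaults to ones."""
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.accumulate(np.ones_like(self.data) if seed is None else seed)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if not node.trainable:
                node.grad = None  # free intermediate buffers


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)
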