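"""Stochastic gradient descent with momentum and L2 regularization.

The update implements the classic heavy-ball form

    v <- momentum * v - lr * (g + 2 * l2 * theta)
    theta <- theta + v

where the ``2 * l2 * theta`` term is the exact gradient of the penalty
``l2 * ||theta||^2`` added to the objective.
"""

from __future__ import annotations

import numpy as np

from .layers import Module

__all__ = ["SGDM"]


class SGDM:
    def __init__(self, model: Module, lr: float, momentum: float = 0.9,
                 l2: float = 0.0, clip_norm: float | None = 10.0):
        if lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        self.params = list(model.parameters())
        self.lr, self.momentum, self.l2 = lr, momentum, l2
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            sq = sum(float(np.sum(p.grad * p.grad)) for p in self.params
                     if p.grad is not None)
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
        for p, v in zip(self.params, self._velocity):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            g = g * scale
            if self.l2:
                g = g + 2.0 * self.l2 * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
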