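"""Stochastic gradient descent with momentum and cosine annealing."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["SGD", "cosine_lr"]


def cosine_lr(epoch: int, total_epochs: int, lr0: float, eta_min: float = 0.0) -> float:
    """Single-cycle cosine-annealed learning rate.

    ``lr = eta_min + 0.5 (lr0 - eta_min) (1 + cos(pi epoch / total))``:
    starts at ``lr0`` (epoch 0), passes the midpoint at the half-way epoch,
    and reaches ``eta_min`` at ``total_epochs``.
    """
    if not 0 <= epoch <= total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs}]")
    return eta_min + 0.5 * (lr0 - eta_min) * (1.0 + math.cos(math.pi * epoch / total_epochs))


class SGD:
    """SGD with classical momentum: v <- mu v - lr g; p <- p + v."""

    def __init__(self, params, lr: float = 0.001, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v
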