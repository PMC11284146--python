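"""Optimisers and learning-rate scheduling."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["Adam", "StepLR"]


class Adam:
    """Adam with decoupled weight decay (the AdamW update).

    The decay term multiplies each parameter by ``1 - lr * weight_decay`` per
    step, independent of the gradient moments.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay:
                p.data *= 1 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class StepLR:
    """Multiply the optimiser's learning rate by ``gamma`` every ``step_size`` epochs."""

    def __init__(self, optimizer: Adam, step_size: int, gamma: float = 0.1):
        self.optimizer = optimizer
        self.step_size = step_size
        self.gamma = gamma
        self.base_lr = optimizer.lr
        self.epoch = 0

    def step(self) -> None:
        """Advance one epoch and update the learning rate."""
        self.set_epoch(self.epoch + 1)

    def set_epoch(self, epoch: int) -> None:
        """Jump to ``epoch`` (0-based) and set the learning rate accordingly."""
        self.epoch = epoch
        self.optimizer.lr = self.base_lr * self.gamma ** (self.epoch // self.step_size)

    @property
    def lr(self) -> float:
        return self.optimizer.lr
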