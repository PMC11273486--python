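"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["SGD"]


class SGD:
    """``v <- m*v + g; p <- p - lr*v`` per parameter.

    ``lr`` may be changed between epochs (step-decay schedules divide it by 10
    every fixed number of epochs).
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
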