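"""Optimizers: SGD with Nesterov momentum and RMSProp, both with L2 decay."""

from __future__ import annotations

import numpy as np

from .layers import Param


class NesterovSGD:
    """Mini-batch gradient descent with Nesterov momentum.

    ``v <- mu * v + g;  w <- w - lr * (g + mu * v)`` with the L2 penalty
    ``d`` folded into the gradient as ``g + d * w``. Learning rate and
    momentum may change every step (cyclical schedule)."""

    def __init__(self, params: list[Param], weight_decay: float = 0.0) -> None:
        self.params = params
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float, momentum: float) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= momentum
            v += g
            p.data -= lr * (g + momentum * v)


class RMSProp:
    def __init__(self, params: list[Param], weight_decay: float = 0.0, rho: float = 0.99, eps: float = 1e-8) -> None:
        self.params = params
        self.weight_decay = weight_decay
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float, momentum: float = 0.0) -> None:
        for p, c in zip(self.params, self.cache):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p.data -= lr * g / (np.sqrt(c) + self.eps)
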