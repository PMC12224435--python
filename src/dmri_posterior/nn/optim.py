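"""Plain-numpy optimizers operating on (parameter, gradient) pairs."""

from __future__ import annotations

import numpy as np


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list, lr: float, momentum: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        for (p, g), v in zip(self.params, self._vel):
            v *= self.momentum
            v -= self.lr * g
            p += v


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(p) for p, _ in params]
        self._v = [np.zeros_like(p) for p, _ in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        bc1 = 1.0 - self.b1**self._t
        bc2 = 1.0 - self.b2**self._t
        for (p, g), m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def make_optimizer(name: str, params: list, lr: float,
                   momentum: float = 0.0):
    if name == "sgd":
        return SGD(params, lr=lr, momentum=momentum)
    if name == "adam":
        return Adam(params, lr=lr)
    raise ValueError(f"unknown optimizer '{name}'")
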