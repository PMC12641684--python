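"""Seeded first-order optimisers for the numpy networks."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGDPoly:
    """SGD with momentum and polynomial learning-rate decay.

    lr_t = lr0 * (1 - t / t_max) ** power, the schedule conventional for
    U-Net-style segmentation training.
    """

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.99,
                 t_max: int = 1000, power: float = 0.9):
        self.params = list(params)
        self.lr0 = lr
        self.momentum = momentum
        self.t_max = max(1, t_max)
        self.power = power
        self.t = 0
        self.buf = [np.zeros_like(p.data) for p in self.params]

    @property
    def lr(self) -> float:
        frac = min(self.t, self.t_max) / self.t_max
        return self.lr0 * (1.0 - frac) ** self.power

    def step(self):
        lr = self.lr
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            b *= self.momentum
            b += p.grad
            p.data -= (lr * b).astype(DTYPE)
        self.t += 1

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
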