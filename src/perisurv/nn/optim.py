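"""Adam with the exponential step-decayed learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam"]


class Adam:
    """Adam; the learning rate at step k is lr0 * decay^floor(k / decay_steps)."""

    def __init__(self, params: list[Param], lr: float = 1e-4, decay: float = 0.96,
                 decay_steps: int = 1000, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr0 = lr
        self.decay = decay
        self.decay_steps = decay_steps
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.step_count = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    @property
    def current_lr(self) -> float:
        return self.lr0 * self.decay ** (self.step_count // self.decay_steps)

    def step(self) -> None:
        lr = self.current_lr
        self.step_count += 1
        t = self.step_count
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1 - self.beta2) * p.grad**2
            mhat = m / (1 - self.beta1**t)
            vhat = v / (1 - self.beta2**t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
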