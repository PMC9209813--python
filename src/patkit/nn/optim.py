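"""Adam optimizer with a reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Standard Adam (Kingma & Ba) on a list of :class:`Parameter`."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer LR after ``patience`` epochs
    without improvement of the monitored value, down to ``min_lr``."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, value: float) -> bool:
        """Report one epoch's monitored value; returns True if LR was cut."""
        if value < self.best:
            self.best = value
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs >= self.patience:
            self.bad_epochs = 0
            new_lr = max(self.opt.lr * self.factor, self.min_lr)
            changed = new_lr < self.opt.lr
            self.opt.lr = new_lr
            return changed
        return False
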