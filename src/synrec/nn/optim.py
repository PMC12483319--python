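"""AdamW optimizer and plateau learning-rate scheduler."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "ReduceLROnPlateau"]


class AdamW:
    """AdamW with decoupled weight decay (defaults: betas (0.9, 0.999), wd 0.01)."""

    def __init__(self, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for key, p in params.items():
            g = grads[key]
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay:
                p *= 1.0 - self.lr * self.weight_decay
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Halve (by `factor`) the lr when validation loss plateaus for `patience` epochs."""

    def __init__(self, optimizer: AdamW, factor=0.5, patience=5, min_lr=1e-7):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> bool:
        """Returns True when the learning rate was reduced this epoch."""
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs >= self.patience:
            self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
            self.bad_epochs = 0
            return True
        return False
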