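"""AdamW with decoupled weight decay."""

from __future__ import annotations

import numpy as np

from .modules import Parameter

__all__ = ["AdamW"]


class AdamW:
    def __init__(self, params, lr=2e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=5e-4):
        self.params: list[Parameter] = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
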