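"""Adam optimizer with optional L1 penalty on convolution weights."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Standard Adam (Kingma & Ba) over a list of parameters.

    ``l1_params``/``l1_weight``: an L1 subgradient ``l1_weight * sign(w)`` is
    added to the gradient of each tensor in ``l1_params`` before the update.
    """

    def __init__(self, params, lr=3e-4, beta1=0.9, beta2=0.999, eps=1e-8,
                 l1_weight=0.0, l1_params=()):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.l1_weight = float(l1_weight)
        self.l1_ids = {id(p) for p in l1_params}
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.l1_weight and id(p) in self.l1_ids:
                g = g + self.l1_weight * np.sign(p.data)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
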