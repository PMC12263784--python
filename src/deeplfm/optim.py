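"""AdamW (decoupled weight decay) for the numpy autodiff parameters."""

from __future__ import annotations

import numpy as np

from ._ad import Tensor


class AdamW:
    """Adam with decoupled weight decay.

    Parameters
    ----------
    params : list of Tensor
        Trainable leaves; updated in place by :meth:`step`.
    lr : float
        Step size (default 0.01, the package-wide training default).
    betas : (float, float)
        Exponential decay rates for the first and second moments.
    eps : float
        Denominator stabiliser.
    weight_decay : float
        Decoupled decay coefficient (0 disables it).
    """

    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        # ``params`` is either a flat list of tensors or a list of
        # {"params": [...], "lr": float} group dicts
        self.params, self._lrs = [], []
        for entry in params:
            if isinstance(entry, dict):
                for p in entry["params"]:
                    self.params.append(p)
                    self._lrs.append(entry.get("lr", lr))
            elif isinstance(entry, Tensor):
                self.params.append(entry)
                self._lrs.append(lr)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, lr, m, v in zip(self.params, self._lrs, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            if self.weight_decay:
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * update
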