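"""Optimizers operating on lists of Param objects."""

from __future__ import annotations

import numpy as np


class SGD:
    """Stochastic gradient descent with classical momentum.

    v <- mu*v - lr*grad ; w <- w + v. With ``momentum=0`` this is plain SGD.
    """

    def __init__(self, params, lr, momentum=0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr, self.momentum = lr, momentum
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


class Adam:
    """Adam with bias correction; betas default to the GAN-friendly (0.5, 0.999)."""

    def __init__(self, params, lr, beta1=0.5, beta2=0.999, eps=1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1t = 1.0 - self.b1**self._t
        b2t = 1.0 - self.b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
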