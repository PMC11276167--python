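"""Adam optimizer (adaptive-moment first-order method) with optional L2
penalty on weight matrices.

The L2 term (``weight_decay``) is added to the gradient of every parameter
of rank >= 2 — weight matrices and recurrent kernels, but not biases or
normalization scales. It is essential here: the slope/interval features are
many and mostly noise-dominated, and without an explicit ridge penalty a
network of this size interpolates the training noise instead of placing the
ordinal class boundaries where they generalize.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        layers: list[Layer],
        lr: float = 5e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                if self.weight_decay and p.ndim >= 2:
                    g = g + self.weight_decay * p
                m = self.m[li][k]
                v = self.v[li][k]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
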