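"""RMSProp optimizer for the segmentation network."""

from __future__ import annotations

import numpy as np


class RMSProp:
    """Root-mean-square-propagation updates.

    ``v <- alpha*v + (1-alpha)*g^2 ; p <- p - lr * g / (sqrt(v) + eps)``
    applied in place to the arrays returned by ``net.named_params()``.
    """

    def __init__(self, net, lr: float = 1e-3, alpha: float = 0.99, eps: float = 1e-8):
        self.net = net
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.state = {name: np.zeros_like(p) for name, p, _ in net.named_params()}

    def step(self) -> None:
        for name, p, g in self.net.named_params():
            v = self.state[name]
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p -= (self.lr * g / (np.sqrt(v) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for _, _, g in self.net.named_params():
            g[...] = 0.0
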