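"""Adam optimiser for the network layers."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with the framework-default moment coefficients.

    ``step`` consumes the gradients each layer stored during ``backward``.
    """

    def __init__(self, network, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.network = network
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for layer, name, arr in self.network.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            key = (id(layer), name)
            m = self._m.setdefault(key, np.zeros_like(arr))
            v = self._v.setdefault(key, np.zeros_like(arr))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / bias1
            vhat = v / bias2
            arr -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(arr.dtype)
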