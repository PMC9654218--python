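"""Network container, classification heads and loss functions."""

from __future__ import annotations

import numpy as np

from .layers import Layer, MultiBranch

__all__ = ["Network", "binary_head_loss", "softmax_head_loss",
           "sigmoid", "softmax"]


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def binary_head_loss(logits, y):
    """Sigmoid + binary cross-entropy on a single-logit head.

    ``logits``: (N, 1); ``y``: (N,) in {0, 1}.  Returns (mean loss, dlogits).
    """
    z = logits[:, 0]
    p = sigmoid(z)
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    dz = ((p - y) / len(y)).astype(logits.dtype)
    return float(loss), dz[:, None]


def softmax_head_loss(logits, y):
    """Softmax + categorical cross-entropy.

    ``logits``: (N, C); ``y``: (N,) integer class indices.
    """
    p = softmax(logits)
    n = len(y)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    dz = p.copy()
    dz[np.arange(n), y] -= 1.0
    return float(loss), (dz / n).astype(logits.dtype)


class Network:
    """A sequential stack of layers with a classification head.

    ``n_classes`` decides the head semantics: 2 -> one sigmoid logit with
    binary cross-entropy, otherwise softmax with categorical cross-entropy.
    """

    def __init__(self, layers: list[Layer], n_classes: int):
        self.layers = layers
        self.n_classes = n_classes

    # -- structure ---------------------------------------------------------
    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, MultiBranch):
                yield from layer.iter_layers()
            yield layer

    def parameters(self):
        """Yield (layer, name, array) for every trainable array."""
        for layer in self.iter_layers():
            for name, arr in layer.params.items():
                yield layer, name, arr

    @property
    def n_params(self) -> int:
        return sum(arr.size for _, _, arr in self.parameters())

    def shape_trace(self, input_shape):
        """Stage shapes (T, E, F) after each top-level layer, without
        allocating activations."""
        trace = [tuple(input_shape)]
        s = tuple(input_shape)
        for layer in self.layers:
            s = layer.out_shape(s)
            trace.append(tuple(s))
        return trace

    # -- compute -----------------------------------------------------------
    def forward(self, x, train=True):
        h = x
        for layer in self.layers:
            h = layer.forward(h, train=train)
        return h[:, 0, 0, :]  # logits (N, units)

    def backward(self, dlogits):
        d = dlogits[:, None, None, :]
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def loss_and_grad(self, x, y):
        logits = self.forward(x, train=True)
        if self.n_classes == 2:
            loss, dlogits = binary_head_loss(logits, y)
        else:
            loss, dlogits = softmax_head_loss(logits, y)
        self.backward(dlogits)
        return loss

    def predict_proba(self, x, batch=256):
        """Class probabilities (N, n_classes), evaluated in inference mode."""
        outs = []
        for i in range(0, len(x), batch):
            logits = self.forward(x[i:i + batch], train=False)
            if self.n_classes == 2:
                p1 = sigmoid(logits[:, 0])
                outs.append(np.column_stack([1 - p1, p1]))
            else:
                outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)

    def predict(self, x, batch=256):
        return self.predict_proba(x, batch=batch).argmax(axis=1)

    # -- state -------------------------------------------------------------
    def get_state(self):
        state = []
        for layer in self.iter_layers():
            entry = {k: v.copy() for k, v in layer.params.items()}
            if hasattr(layer, "running_mean"):
                entry["__running_mean"] = layer.running_mean.copy()
                entry["__running_var"] = layer.running_var.copy()
            state.append(entry)
        return state

    def set_state(self, state):
        for layer, entry in zip(self.iter_layers(), state):
            for k in layer.params:
                layer.params[k] = entry[k].copy()
            if hasattr(layer, "running_mean"):
                layer.running_mean = entry["__running_mean"].copy()
                layer.running_var = entry["__running_var"].copy()
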