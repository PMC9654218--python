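"""Feed-forward network primitives for EEG-shaped tensors.

All layers operate on arrays of shape ``(N, T, E, F)`` — batch, time samples,
electrode channels, feature maps — mirroring the channels-last layout of the
frameworks this family of EEG models is usually written in.  Every layer
implements ``forward``/``backward`` (reverse-mode gradients for all trainable
arrays plus the input) and ``out_shape`` so that complete architectures can be
shape-checked and parameter-counted without allocating weights.

Only what the model zoo needs is implemented; this is not a general autograd.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..exceptions import ConstructionError, ShapeError

__all__ = [
    "Layer", "TemporalConv", "TemporalDepthwiseConv", "SpatialConv",
    "DepthwiseSpatialConv", "PointwiseConv", "BatchNorm", "AvgPoolTime",
    "MaxPoolTime", "Activation", "SEBlock", "MultiBranch", "Flatten", "Dense",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: trainable arrays live in ``params``, gradients in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=True):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def out_shape(self, shape):
        """Map an input ``(T, E, F)`` stage shape to the output stage shape."""
        return shape

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def zero_grads(self):
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def _pad_amounts(k: int) -> tuple[int, int]:
    # 'same' padding for stride 1; the extra sample goes on the right.
    left = (k - 1) // 2
    return left, (k - 1) - left


class TemporalConv(Layer):
    """Convolution along the time axis with a ``1 x k`` kernel per channel pair."""

    def __init__(self, in_f, out_f, k, padding="same", bias=True,
                 rng=None, dtype=np.float32):
        super().__init__()
        if k < 1:
            raise ConstructionError("temporal kernel must span >= 1 sample")
        self.in_f, self.out_f, self.k, self.padding = in_f, out_f, k, padding
        self.use_bias = bias
        rng = rng or np.random.default_rng()
        self.params["W"] = glorot_uniform(
            rng, (k, in_f, out_f), k * in_f, k * out_f, dtype)
        if bias:
            self.params["b"] = np.zeros(out_f, dtype=dtype)

    def _t_out(self, T):
        if self.padding == "same":
            return T
        t = T - self.k + 1
        if t < 1:
            raise ConstructionError(
                f"temporal conv (k={self.k}) exhausts a {T}-sample axis")
        return t

    def out_shape(self, shape):
        T, E, F = shape
        if F != self.in_f:
            raise ConstructionError(
                f"temporal conv expects {self.in_f} feature maps, got {F}")
        return (self._t_out(T), E, self.out_f)

    # im2col is only worthwhile while the unrolled buffer fits comfortably
    # in memory; above this element count fall back to a per-tap loop.
    _COLS_LIMIT = 150_000_000

    def _prepare(self, x):
        N, T, E, F = x.shape
        if self.padding == "same":
            lo, _ = _pad_amounts(self.k)
            xp = np.zeros((N, T + self.k - 1, E, F), dtype=x.dtype)
            xp[:, lo:lo + T] = x
            t_out = T
        else:
            xp, t_out = x, self._t_out(T)
        return xp, t_out, T

    def forward(self, x, train=True):
        W = self.params["W"]
        xp, t_out, T = self._prepare(x)
        self._t_out_saved, self._T_in = t_out, T
        N, _, E, F = xp.shape
        if N * t_out * E * F * self.k <= self._COLS_LIMIT:
            win = sliding_window_view(xp, self.k, axis=1)  # (N,t,E,F,k)
            cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 3))
            cols = cols.reshape(-1, self.k * F)
            self._cols, self._xp = cols, None
            y = cols @ W.reshape(self.k * F, self.out_f)
            y = y.reshape(N, t_out, E, self.out_f)
        else:
            self._cols, self._xp = None, xp
            y = np.zeros((N, t_out, E, self.out_f), dtype=x.dtype)
            for j in range(self.k):
                y += np.tensordot(xp[:, j:j + t_out], W[j], axes=([3], [0]))
        if self.use_bias:
            y += self.params["b"]
        return y

    def backward(self, dy):
        W = self.params["W"]
        t_out, T = self._t_out_saved, self._T_in
        N, _, E, _ = dy.shape
        F = self.in_f
        dy2 = np.ascontiguousarray(dy).reshape(-1, self.out_f)
        if self._cols is not None:
            cols = self._cols
            self.grads["W"] = (cols.T @ dy2).reshape(self.k, F, self.out_f)
            dcols = dy2 @ W.reshape(self.k * F, self.out_f).T
            dcols = dcols.reshape(N, t_out, E, self.k, F)
            Tp = T + self.k - 1 if self.padding == "same" else T
            dxp = np.zeros((N, Tp, E, F), dtype=dy.dtype)
            for j in range(self.k):
                dxp[:, j:j + t_out] += dcols[:, :, :, j, :]
        else:
            xp = self._xp
            dW = np.empty_like(W)
            dxp = np.zeros_like(xp)
            dyr = dy2.reshape(dy.shape)
            for j in range(self.k):
                seg = xp[:, j:j + t_out]
                dW[j] = np.tensordot(seg, dyr, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, j:j + t_out] += np.tensordot(dyr, W[j], axes=([3], [1]))
            self.grads["W"] = dW
        if self.use_bias:
            self.grads["b"] = dy2.sum(axis=0)
        if self.padding == "same":
            lo, _ = _pad_amounts(self.k)
            return dxp[:, lo:lo + T]
        return dxp


class TemporalDepthwiseConv(Layer):
    """Per-feature-map temporal convolution (the depthwise half of a
    separable temporal convolution)."""

    def __init__(self, f, k, padding="same", bias=False, rng=None,
                 dtype=np.float32):
        super().__init__()
        self.f, self.k, self.padding, self.use_bias = f, k, padding, bias
        rng = rng or np.random.default_rng()
        self.params["W"] = glorot_uniform(rng, (k, f), k, k, dtype)
        if bias:
            self.params["b"] = np.zeros(f, dtype=dtype)

    def out_shape(self, shape):
        T, E, F = shape
        if F != self.f:
            raise ConstructionError("depthwise temporal conv feature mismatch")
        t = T if self.padding == "same" else T - self.k + 1
        if t < 1:
            raise ConstructionError("depthwise temporal conv exhausts time axis")
        return (t, E, F)

    def forward(self, x, train=True):
        N, T, E, F = x.shape
        W = self.params["W"]
        if self.padding == "same":
            lo, _ = _pad_amounts(self.k)
            xp = np.zeros((N, T + self.k - 1, E, F), dtype=x.dtype)
            xp[:, lo:lo + T] = x
            t_out = T
        else:
            xp, t_out = x, T - self.k + 1
        self._xp, self._t_out_saved, self._T_in = xp, t_out, T
        y = np.zeros((N, t_out, E, F), dtype=x.dtype)
        for j in range(self.k):
            y += xp[:, j:j + t_out] * W[j]
        if self.use_bias:
            y += self.params["b"]
        return y

    def backward(self, dy):
        W = self.params["W"]
        xp, t_out, T = self._xp, self._t_out_saved, self._T_in
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for j in range(self.k):
            dW[j] = (xp[:, j:j + t_out] * dy).sum(axis=(0, 1, 2))
            dxp[:, j:j + t_out] += dy * W[j]
        self.grads["W"] = dW
        if self.use_bias:
            self.grads["b"] = dy.sum(axis=(0, 1, 2))
        if self.padding == "same":
            lo, _ = _pad_amounts(self.k)
            return dxp[:, lo:lo + T]
        return dxp


class SpatialConv(Layer):
    """Full-span spatial convolution ``(E x 1)``: collapses the electrode axis."""

    def __init__(self, E, in_f, out_f, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        self.E, self.in_f, self.out_f, self.use_bias = E, in_f, out_f, bias
        rng = rng or np.random.default_rng()
        self.params["W"] = glorot_uniform(
            rng, (E, in_f, out_f), E * in_f, E * out_f, dtype)
        if bias:
            self.params["b"] = np.zeros(out_f, dtype=dtype)

    def out_shape(self, shape):
        T, E, F = shape
        if E != self.E or F != self.in_f:
            raise ConstructionError(
                f"spatial conv built for ({self.E} ch, {self.in_f} maps), "
                f"input has ({E}, {F})")
        return (T, 1, self.out_f)

    def forward(self, x, train=True):
        self._x = x
        y = np.tensordot(x, self.params["W"], axes=([2, 3], [0, 1]))
        if self.use_bias:
            y += self.params["b"]
        return y[:, :, None, :]

    def backward(self, dy):
        dysq = dy[:, :, 0, :]
        self.grads["W"] = np.tensordot(self._x, dysq, axes=([0, 1], [0, 1]))
        if self.use_bias:
            self.grads["b"] = dysq.sum(axis=(0, 1))
        return np.einsum("nto,eio->ntei", dysq, self.params["W"])


class DepthwiseSpatialConv(Layer):
    """Depthwise spatial filtering: ``mult`` full-span electrode filters per
    incoming temporal feature map; output feature order is map-major."""

    def __init__(self, E, in_f, mult, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        self.E, self.in_f, self.mult, self.use_bias = E, in_f, mult, bias
        rng = rng or np.random.default_rng()
        self.params["W"] = glorot_uniform(rng, (E, in_f, mult), E, E * mult, dtype)
        if bias:
            self.params["b"] = np.zeros(in_f * mult, dtype=dtype)

    def out_shape(self, shape):
        T, E, F = shape
        if E != self.E or F != self.in_f:
            raise ConstructionError(
                f"depthwise spatial conv built for ({self.E} ch, {self.in_f} "
                f"maps), input has ({E}, {F})")
        return (T, 1, self.in_f * self.mult)

    def forward(self, x, train=True):
        self._x = x
        y = np.einsum("ntei,eim->ntim", x, self.params["W"], optimize=True)
        y = y.reshape(x.shape[0], x.shape[1], 1, self.in_f * self.mult)
        if self.use_bias:
            y += self.params["b"]
        return np.ascontiguousarray(y)

    def backward(self, dy):
        N, T = dy.shape[:2]
        dyr = dy.reshape(N, T, self.in_f, self.mult)
        self.grads["W"] = np.einsum("ntei,ntim->eim", self._x, dyr,
                                    optimize=True)
        if self.use_bias:
            self.grads["b"] = dy.sum(axis=(0, 1, 2))
        return np.einsum("ntim,eim->ntei", dyr, self.params["W"],
                         optimize=True)


class PointwiseConv(Layer):
    """1x1 feature mixing (the pointwise half of a separable convolution)."""

    def __init__(self, in_f, out_f, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        self.in_f, self.out_f, self.use_bias = in_f, out_f, bias
        rng = rng or np.random.default_rng()
        self.params["W"] = glorot_uniform(rng, (in_f, out_f), in_f, out_f, dtype)
        if bias:
            self.params["b"] = np.zeros(out_f, dtype=dtype)

    def out_shape(self, shape):
        T, E, F = shape
        if F != self.in_f:
            raise ConstructionError("pointwise conv feature mismatch")
        return (T, E, self.out_f)

    def forward(self, x, train=True):
        self._x = x
        y = x @ self.params["W"]
        if self.use_bias:
            y += self.params["b"]
        return y

    def backward(self, dy):
        self.grads["W"] = np.tensordot(self._x, dy, axes=([0, 1, 2], [0, 1, 2]))
        if self.use_bias:
            self.grads["b"] = dy.sum(axis=(0, 1, 2))
        return dy @ self.params["W"].T


class BatchNorm(Layer):
    """Per-feature-map batch normalisation (trainable scale and shift only
    count as parameters; running statistics are buffers).

    Momentum 0.9: the reference experiments run tens of epochs on a handful
    of mini-batches, so the running statistics must track the trained
    activations within ~50 steps or inference-mode accuracy decouples from
    training-mode accuracy."""

    def __init__(self, f, momentum=0.9, eps=1e-3, dtype=np.float32):
        super().__init__()
        self.f, self.momentum, self.eps = f, momentum, eps
        self.params["gamma"] = np.ones(f, dtype=dtype)
        self.params["beta"] = np.zeros(f, dtype=dtype)
        self.running_mean = np.zeros(f, dtype=dtype)
        self.running_var = np.ones(f, dtype=dtype)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = np.maximum((x * x).mean(axis=(0, 1, 2)) - mean * mean, 0.0)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(
                self.running_mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._xhat, self._std = xhat, std
        self._m = x.shape[0] * x.shape[1] * x.shape[2]
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, std, m = self._xhat, self._std, self._m
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dy.sum(axis=(0, 1, 2))
        g = self.params["gamma"]
        dmean = dy.mean(axis=(0, 1, 2))
        dproj = (dy * xhat).mean(axis=(0, 1, 2))
        return (g / std) * (dy - dmean - xhat * dproj)


class _PoolTime(Layer):
    def __init__(self, size, stride=None):
        super().__init__()
        if size < 1:
            raise ConstructionError("pool size must be >= 1")
        self.size = size
        self.stride = stride or size

    def out_shape(self, shape):
        T, E, F = shape
        t = (T - self.size) // self.stride + 1
        if t < 1:
            raise ConstructionError(
                f"pooling (size {self.size}) exhausts a {T}-sample time axis")
        return (t, E, F)

    def _windows(self, x):
        # (N, T_out, E, F, size) strided view
        return sliding_window_view(x, self.size, axis=1)[:, ::self.stride]


class AvgPoolTime(_PoolTime):
    """Average pooling along time."""

    def forward(self, x, train=True):
        self._in_shape = x.shape
        if self.stride == self.size:
            N, T, E, F = x.shape
            t_out = T // self.size
            self._t_out = t_out
            used = x[:, :t_out * self.size]
            return used.reshape(N, t_out, self.size, E, F).mean(axis=2)
        win = self._windows(x)
        self._t_out = win.shape[1]
        return win.mean(axis=-1)

    def backward(self, dy):
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        share = dy / self.size
        if self.stride == self.size:
            N, T, E, F = self._in_shape
            t_used = self._t_out * self.size
            view = dx[:, :t_used].reshape(N, self._t_out, self.size, E, F)
            view[:] = share[:, :, None]
            return dx
        starts = np.arange(self._t_out) * self.stride
        for j in range(self.size):
            dx[:, starts + j] += share
        return dx


class MaxPoolTime(_PoolTime):
    """Max pooling along time."""

    def forward(self, x, train=True):
        self._in_shape = x.shape
        win = self._windows(x)
        self._t_out = win.shape[1]
        self._arg = win.argmax(axis=-1)
        return win.max(axis=-1)

    def backward(self, dy):
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        starts = np.arange(self._t_out) * self.stride
        for j in range(self.size):
            mask = self._arg == j
            contrib = np.where(mask, dy, 0.0)
            dx[:, starts + j] += contrib
        return dx


class Activation(Layer):
    """Elementwise nonlinearity: relu, elu, square or the clipped log used by
    band-power-style shallow networks."""

    def __init__(self, kind, eps=1e-6):
        super().__init__()
        if kind not in ("relu", "elu", "square", "log", "identity"):
            raise ConstructionError(f"unknown activation {kind!r}")
        self.kind, self.eps = kind, eps

    def forward(self, x, train=True):
        self._x = x
        if self.kind == "relu":
            y = np.maximum(x, 0)
            self._mask = np.sign(y)
            return y
        if self.kind == "elu":
            self._y = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
            return self._y
        if self.kind == "square":
            return x * x
        if self.kind == "log":
            self._clipped = np.maximum(x, self.eps)
            return np.log(self._clipped)
        return x

    def backward(self, dy):
        x = self._x
        if self.kind == "relu":
            return dy * self._mask
        if self.kind == "elu":
            return dy * np.where(x > 0, 1.0, self._y + 1.0)
        if self.kind == "square":
            return dy * 2.0 * x
        if self.kind == "log":
            return dy * (x > self.eps) / self._clipped
        return dy


class SEBlock(Layer):
    """Squeeze-and-excitation gating over feature maps.

    Global average over time (and space) squeezes to one descriptor per map; a
    bottleneck of width ``max(1, floor(f / r))`` with ReLU and a sigmoid
    expansion produce per-map gates in (0, 1) that rescale the input.
    """

    def __init__(self, f, r=16, bias=False, rng=None, dtype=np.float32):
        super().__init__()
        self.f, self.r, self.use_bias = f, r, bias
        self.bottleneck = max(1, f // r)
        rng = rng or np.random.default_rng()
        b = self.bottleneck
        self.params["W1"] = glorot_uniform(rng, (f, b), f, b, dtype)
        self.params["W2"] = glorot_uniform(rng, (b, f), b, f, dtype)
        if bias:
            self.params["b1"] = np.zeros(b, dtype=dtype)
            self.params["b2"] = np.zeros(f, dtype=dtype)

    def forward(self, x, train=True):
        self._x = x
        s = x.mean(axis=(1, 2))
        z1 = s @ self.params["W1"]
        if self.use_bias:
            z1 += self.params["b1"]
        h = np.maximum(z1, 0)
        z2 = h @ self.params["W2"]
        if self.use_bias:
            z2 += self.params["b2"]
        g = 1.0 / (1.0 + np.exp(-z2))
        self._s, self._z1, self._h, self._g = s, z1, h, g
        return x * g[:, None, None, :]

    @property
    def gates(self):
        return self._g

    def backward(self, dy):
        x, s, z1, h, g = self._x, self._s, self._z1, self._h, self._g
        dx = dy * g[:, None, None, :]
        dg = np.einsum("ntef,ntef->nf", dy, x, optimize=True)
        dz2 = dg * g * (1 - g)
        self.grads["W2"] = h.T @ dz2
        if self.use_bias:
            self.grads["b2"] = dz2.sum(axis=0)
        dh = dz2 @ self.params["W2"].T
        dz1 = dh * (z1 > 0)
        self.grads["W1"] = s.T @ dz1
        if self.use_bias:
            self.grads["b1"] = dz1.sum(axis=0)
        ds = dz1 @ self.params["W1"].T
        m = x.shape[1] * x.shape[2]
        return dx + ds[:, None, None, :] / m


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate, seed=0):
        super().__init__()
        if not 0 <= rate < 1:
            raise ConstructionError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x, train=True):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask.astype(x.dtype)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask.astype(dy.dtype)


class MultiBranch(Layer):
    """Run parallel layer chains on the same input and concatenate their
    feature maps; all branches must agree on time and space dimensions."""

    def __init__(self, branches):
        super().__init__()
        self.branches = branches

    @property
    def n_params(self):
        return sum(l.n_params for br in self.branches for l in br)

    def iter_layers(self):
        for br in self.branches:
            yield from br

    def out_shape(self, shape):
        outs = []
        for br in self.branches:
            s = shape
            for layer in br:
                s = layer.out_shape(s)
            outs.append(s)
        te = {(t, e) for t, e, _ in outs}
        if len(te) != 1:
            raise ConstructionError(
                f"branch time/space dimensions differ: {sorted(te)}")
        t, e = te.pop()
        return (t, e, sum(f for _, _, f in outs))

    def forward(self, x, train=True):
        ys, widths = [], []
        for br in self.branches:
            h = x
            for layer in br:
                h = layer.forward(h, train=train)
            ys.append(h)
            widths.append(h.shape[-1])
        self._widths = widths
        return np.concatenate(ys, axis=-1)

    def backward(self, dy):
        dx = None
        offset = 0
        for br, w in zip(self.branches, self._widths):
            d = dy[..., offset:offset + w]
            offset += w
            for layer in reversed(br):
                d = layer.backward(d)
            dx = d if dx is None else dx + d
        return dx


class Flatten(Layer):
    def out_shape(self, shape):
        T, E, F = shape
        return (1, 1, T * E * F)

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], 1, 1, -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Affine map on flattened features: (N, 1, 1, in) -> (N, 1, 1, out)."""

    def __init__(self, in_f, out_f, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        self.in_f, self.out_f, self.use_bias = in_f, out_f, bias
        rng = rng or np.random.default_rng()
        self.params["W"] = glorot_uniform(rng, (in_f, out_f), in_f, out_f, dtype)
        if bias:
            self.params["b"] = np.zeros(out_f, dtype=dtype)

    def out_shape(self, shape):
        T, E, F = shape
        if T != 1 or E != 1:
            raise ConstructionError("dense layer expects flattened input")
        if F != self.in_f:
            raise ShapeError(
                f"dense layer expects width {self.in_f}, got {F}")
        return (1, 1, self.out_f)

    def forward(self, x, train=True):
        self._x = x
        y = x @ self.params["W"]
        if self.use_bias:
            y += self.params["b"]
        return y

    def backward(self, dy):
        self.grads["W"] = np.tensordot(self._x, dy, axes=([0, 1, 2], [0, 1, 2]))
        if self.use_bias:
            self.grads["b"] = dy.sum(axis=(0, 1, 2))
        return dy @ self.params["W"].T
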