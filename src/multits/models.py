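"""Declarative architecture specs and builders for the EEG model zoo.

Four families are supported:

``multits``
    Multi-kernel temporal + separable spatial convolution network with
    squeeze-and-excitation (SE) recalibration after both stages.  Four
    parallel temporal convolutions (default 25/50/100/200 ms kernels, 24
    filters each, zero-padded to equal length) are concatenated into
    ``Fte = 4 x 24 = 96`` temporal feature maps; a depthwise spatial
    convolution (feature multiplier 2) collapses the electrode axis; a
    pointwise convolution mixes down to ``Fsp = 64`` temporal-spatial maps.
``deep`` / ``shallow``
    The deep and shallow reference ConvNets for raw-EEG decoding, adapted to
    the 2 s / 200 Hz input with 24/24/48+96+192 and 40/40 filter counts.
``eegnet``
    The compact separable-convolution network (32 temporal filters,
    depthwise multiplier 2, separable stage of width 64).

``multikernelify`` rewrites a non-``multits`` spec so its first temporal
convolution becomes the four-branch multi-kernel block (per-branch filters =
half the original temporal filters) while halving the spatial stage.

Kernel lengths are stored in milliseconds and converted per sampling rate,
so the same spec covers identical time scales on differently sampled data.

Layer conventions (bias and batch-norm placement, SE dense layers without
bias, pooling sizes) follow the configurations documented in
``docs/methods.md``; with those conventions the closed-form per-stage counts
reproduce the published trainable-parameter totals for every family at the
2 s x 200 Hz x 62-channel input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .exceptions import ConfigError, ConstructionError, ParameterError
from .nn import (
    Activation, AvgPoolTime, BatchNorm, Dense, DepthwiseSpatialConv, Dropout,
    Flatten, MaxPoolTime, MultiBranch, Network, PointwiseConv, SEBlock,
    SpatialConv, TemporalConv, TemporalDepthwiseConv,
)

__all__ = [
    "ModelSpec", "StageShape", "ms_to_samples", "build_model",
    "multikernelify", "count_trainable_params", "closed_form_param_count",
    "min_frequency_covered", "FAMILIES",
]

FAMILIES = ("multits", "deep", "shallow", "eegnet")


class StageShape(NamedTuple):
    """(time samples, space channels, feature maps) at one network stage."""

    time: int
    space: int
    features: int


def ms_to_samples(ms: float, fs: float) -> int:
    """Kernel duration in ms -> sample count (nearest integer, ties up, >= 1).

    25 ms at 200 Hz -> 5 samples; 200 ms at 200 Hz -> 40 samples.
    """
    if ms <= 0 or fs <= 0:
        raise ParameterError("ms and fs must be positive")
    return max(1, int(math.floor(ms * fs / 1000.0 + 0.5)))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one architecture.

    ``None`` fields take family defaults on :meth:`resolve`.  ``pool_spec``
    is a tuple of ``(size, stride)`` time poolings, one per pooling stage of
    the family.
    """

    family: str = "multits"
    fs: float = 200.0
    window_s: float = 2.0
    n_channels: int = 62
    n_classes: int = 2
    seed: int = 0
    # multi-kernel temporal block (multits and reformed families)
    branch_kernels_ms: Optional[Sequence[float]] = None
    filters_per_branch: Optional[int] = None
    # single-kernel temporal stage (deep / shallow / eegnet)
    temporal_filters: Optional[int] = None
    temporal_kernel_ms: Optional[float] = None
    stage_kernel_ms: Optional[float] = None   # deep's later conv blocks
    sep_kernel_ms: Optional[float] = None     # eegnet separable temporal kernel
    # spatial stage
    feature_multiplier: int = 2
    spatial_filters: Optional[int] = None
    se_ratio: int = 16
    use_se: bool = True
    dropout: Optional[float] = None
    pool_spec: Optional[Sequence[Sequence[int]]] = None
    reformed: bool = False

    _DEFAULTS = {
        "multits": dict(branch_kernels_ms=(25.0, 50.0, 100.0, 200.0),
                        filters_per_branch=24, spatial_filters=64,
                        pool_spec=((4, 4), (4, 4)), dropout=0.0),
        "deep": dict(temporal_filters=24, temporal_kernel_ms=20.0,
                     stage_kernel_ms=30.0, spatial_filters=24,
                     pool_spec=((3, 3), (3, 3), (3, 3), (3, 3)), dropout=0.0),
        "shallow": dict(temporal_filters=40, temporal_kernel_ms=125.0,
                        spatial_filters=40, pool_spec=((75, 15),), dropout=0.0),
        "eegnet": dict(temporal_filters=32, temporal_kernel_ms=500.0,
                       sep_kernel_ms=80.0, spatial_filters=64,
                       pool_spec=((4, 4), (8, 8)), dropout=0.25),
    }

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}")
        if self.n_classes not in (2, 3):
            raise ParameterError("n_classes must be 2 or 3")
        if self.fs <= 0 or self.window_s <= 0 or self.n_channels < 1:
            raise ParameterError("fs, window_s and n_channels must be positive")

    def resolve(self) -> "ModelSpec":
        """Fill family defaults for every ``None`` field."""
        defaults = dict(self._DEFAULTS[self.family])
        if self.reformed:
            defaults.setdefault("branch_kernels_ms", (25.0, 50.0, 100.0, 200.0))
        updates = {k: v for k, v in defaults.items()
                   if getattr(self, k) is None}
        return replace(self, **updates) if updates else self

    # -- derived quantities ------------------------------------------------
    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def input_shape(self) -> StageShape:
        return StageShape(self.window_samples, self.n_channels, 1)

    def branch_kernels_samples(self) -> list[int]:
        spec = self.resolve()
        if spec.branch_kernels_ms is None:
            raise ConfigError("spec has no multi-kernel branches")
        return [ms_to_samples(ms, spec.fs) for ms in spec.branch_kernels_ms]

    @property
    def fte(self) -> int:
        """Total temporal feature maps after branch concatenation."""
        spec = self.resolve()
        if spec.family == "multits" or spec.reformed:
            return spec.filters_per_branch * len(spec.branch_kernels_ms)
        return spec.temporal_filters

    @property
    def head_units(self) -> int:
        return 1 if self.n_classes == 2 else 3

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = [list(x) if isinstance(x, tuple) else x for x in v]
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown ModelSpec keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("branch_kernels_ms", "pool_spec"):
            if d.get(key) is not None:
                d[key] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x
                               for x in d[key]) if key == "pool_spec" else \
                    tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def multikernel_temporal_block(spec: ModelSpec, rng, *, in_f=1,
                               bias=True, dtype=np.float32):
    """Four parallel zero-padded temporal convolutions concatenated on the
    feature axis, followed by ReLU."""
    spec = spec.resolve()
    branches = [[TemporalConv(in_f, spec.filters_per_branch, k, "same",
                              bias=bias, rng=rng, dtype=dtype)]
                for k in spec.branch_kernels_samples()]
    return [MultiBranch(branches)]


def se_block(features_in: int, r: int, rng=None, dtype=np.float32) -> SEBlock:
    """Squeeze-and-excitation gate with bottleneck ``max(1, floor(f/r))``."""
    return SEBlock(features_in, r=r, bias=False, rng=rng, dtype=dtype)


def separable_spatial_block(spec: ModelSpec, rng, dtype=np.float32):
    """Depthwise full-span spatial filtering (multiplier ``m``) followed by
    pointwise mixing down to the spatial filter count."""
    spec = spec.resolve()
    fte = spec.fte
    dw_out = fte * spec.feature_multiplier
    return [
        DepthwiseSpatialConv(spec.n_channels, fte, spec.feature_multiplier,
                             bias=True, rng=rng, dtype=dtype),
        BatchNorm(dw_out, dtype=dtype),
        Activation("relu"),
        PointwiseConv(dw_out, spec.spatial_filters, bias=True, rng=rng,
                      dtype=dtype),
        BatchNorm(spec.spatial_filters, dtype=dtype),
        Activation("relu"),
    ]


def classifier_head(n_classes: int, in_width: int, rng, dtype=np.float32):
    """Flatten + single affine map; 2 classes -> 1 sigmoid logit,
    3 classes -> 3 softmax logits."""
    if n_classes not in (2, 3):
        raise ParameterError("classification head supports 2 or 3 classes")
    units = 1 if n_classes == 2 else 3
    return [Flatten(), Dense(in_width, units, bias=True, rng=rng, dtype=dtype)]


def _flat_width(layers, input_shape) -> int:
    s = tuple(input_shape)
    for layer in layers:
        s = layer.out_shape(s)
    return s[0] * s[1] * s[2]


def _build_multits(spec, rng, dtype):
    fte = spec.fte
    (p1, s1), (p2, s2) = spec.pool_spec
    # ReLU -> pool -> SE -> BN: the SE squeeze sees non-negative pooled
    # activation magnitudes (the reference SE formulation); normalisation
    # afterwards absorbs the average gate scale without erasing the
    # per-sample modulation
    layers = multikernel_temporal_block(spec, rng, dtype=dtype)
    layers += [Activation("relu"), AvgPoolTime(p1, s1)]
    if spec.use_se:
        layers.append(se_block(fte, spec.se_ratio, rng, dtype))
    layers.append(BatchNorm(fte, dtype=dtype))
    layers += separable_spatial_block(spec, rng, dtype)
    layers.append(AvgPoolTime(p2, s2))
    if spec.use_se:
        layers.append(se_block(spec.spatial_filters, spec.se_ratio, rng, dtype))
    layers += classifier_head(spec.n_classes,
                              _flat_width(layers, spec.input_shape), rng, dtype)
    return layers


def _build_deep(spec, rng, dtype):
    E = spec.n_channels
    kl = ms_to_samples(spec.stage_kernel_ms, spec.fs)
    fs_ = spec.spatial_filters
    stage_filters = (2 * fs_, 4 * fs_, 8 * fs_)
    pools = list(spec.pool_spec)
    if spec.reformed:
        fte = spec.fte
        layers = multikernel_temporal_block(spec, rng, dtype=dtype)
        layers += [BatchNorm(fte, dtype=dtype), Activation("relu")]
    else:
        k1 = ms_to_samples(spec.temporal_kernel_ms, spec.fs)
        fte = spec.temporal_filters
        layers = [TemporalConv(1, fte, k1, "valid", bias=True, rng=rng,
                               dtype=dtype),
                  BatchNorm(fte, dtype=dtype)]
    p, s = pools[0]
    layers += [SpatialConv(E, fte, fs_, bias=True, rng=rng, dtype=dtype),
               BatchNorm(fs_, dtype=dtype), Activation("elu"),
               MaxPoolTime(p, s)]
    prev = fs_
    for f, (p, s) in zip(stage_filters, pools[1:]):
        layers += [TemporalConv(prev, f, kl, "valid", bias=True, rng=rng,
                                dtype=dtype),
                   BatchNorm(f, dtype=dtype), Activation("elu"),
                   MaxPoolTime(p, s)]
        prev = f
    layers += classifier_head(spec.n_classes,
                              _flat_width(layers, spec.input_shape), rng, dtype)
    return layers


def _build_shallow(spec, rng, dtype):
    E = spec.n_channels
    fs_ = spec.spatial_filters
    (p, s), = spec.pool_spec
    if spec.reformed:
        fte = spec.fte
        layers = multikernel_temporal_block(spec, rng, dtype=dtype)
        layers += [BatchNorm(fte, dtype=dtype)]
    else:
        k1 = ms_to_samples(spec.temporal_kernel_ms, spec.fs)
        fte = spec.temporal_filters
        layers = [TemporalConv(1, fte, k1, "valid", bias=True, rng=rng,
                               dtype=dtype),
                  BatchNorm(fte, dtype=dtype)]
    layers += [SpatialConv(E, fte, fs_, bias=True, rng=rng, dtype=dtype),
               BatchNorm(fs_, dtype=dtype),
               Activation("square"), AvgPoolTime(p, s), Activation("log")]
    layers += classifier_head(spec.n_classes,
                              _flat_width(layers, spec.input_shape), rng, dtype)
    return layers


def _build_eegnet(spec, rng, dtype):
    E = spec.n_channels
    q = ms_to_samples(spec.sep_kernel_ms, spec.fs)
    (p1, s1), (p2, s2) = spec.pool_spec
    drop = spec.dropout or 0.0
    if spec.reformed:
        # Multi-kernel block inserted as-is (bias, no norm); the separable
        # stage follows the reference-code convention (no pointwise bias).
        fte = spec.fte
        layers = multikernel_temporal_block(spec, rng, dtype=dtype)
        layers += [Activation("relu")]
        pw_bias = False
    else:
        k1 = ms_to_samples(spec.temporal_kernel_ms, spec.fs)
        fte = spec.temporal_filters
        layers = [TemporalConv(1, fte, k1, "same", bias=True, rng=rng,
                               dtype=dtype),
                  BatchNorm(fte, dtype=dtype)]
        pw_bias = True
    dw_out = fte * spec.feature_multiplier
    layers += [DepthwiseSpatialConv(E, fte, spec.feature_multiplier,
                                    bias=True, rng=rng, dtype=dtype),
               BatchNorm(dw_out, dtype=dtype), Activation("elu"),
               AvgPoolTime(p1, s1)]
    if drop:
        layers.append(Dropout(drop, seed=spec.seed + 101))
    layers += [TemporalDepthwiseConv(dw_out, q, "same", bias=False, rng=rng,
                                     dtype=dtype),
               PointwiseConv(dw_out, spec.spatial_filters, bias=pw_bias,
                             rng=rng, dtype=dtype),
               BatchNorm(spec.spatial_filters, dtype=dtype), Activation("elu"),
               AvgPoolTime(p2, s2)]
    if drop:
        layers.append(Dropout(drop, seed=spec.seed + 103))
    layers += classifier_head(spec.n_classes,
                              _flat_width(layers, spec.input_shape), rng, dtype)
    return layers


_BUILDERS = {"multits": _build_multits, "deep": _build_deep,
             "shallow": _build_shallow, "eegnet": _build_eegnet}


def build_model(spec: ModelSpec, dtype=np.float32) -> Network:
    """Instantiate a trainable network from a spec.

    Initialisation is Glorot-uniform, deterministic for a fixed
    ``spec.seed``.  Raises :class:`ConstructionError` naming the stage when
    the shape algebra underflows (e.g. pooling exhausts the time axis).
    """
    spec = spec.resolve()
    rng = np.random.default_rng(spec.seed)
    layers = _BUILDERS[spec.family](spec, rng, dtype)
    net = Network(layers, spec.n_classes)
    net.shape_trace(spec.input_shape)  # validates the full stage algebra
    return net


def multikernelify(spec: ModelSpec) -> ModelSpec:
    """Reform a single-kernel family: the first temporal convolution becomes
    the four-branch multi-kernel block (per-branch filters = half the
    original temporal filters) and the spatial stage is halved."""
    if spec.family == "multits":
        raise ParameterError("the multits family is already multi-kernel")
    if spec.reformed:
        raise ParameterError("spec is already reformed")
    spec = spec.resolve()
    return replace(
        spec, reformed=True,
        branch_kernels_ms=(25.0, 50.0, 100.0, 200.0),
        filters_per_branch=spec.temporal_filters // 2,
        spatial_filters=spec.spatial_filters // 2,
    )


def count_trainable_params(model: Network) -> int:
    """Exact count of optimisable scalars in a built network (weights,
    biases, normalisation scale/shift; running statistics excluded)."""
    return model.n_params


def min_frequency_covered(spec: ModelSpec) -> float:
    """Lowest frequency whose full cycle fits inside the longest temporal
    kernel: ``fs / longest kernel length in samples``."""
    spec = spec.resolve()
    if spec.family == "multits" or spec.reformed:
        longest = max(spec.branch_kernels_samples())
    else:
        longest = ms_to_samples(spec.temporal_kernel_ms, spec.fs)
    return spec.fs / longest


# ---------------------------------------------------------------------------
# closed-form parameter counting (independent of the layer objects)
# ---------------------------------------------------------------------------

def _pool_len(t: int, p: int, s: int) -> int:
    out = (t - p) // s + 1
    if out < 1:
        raise ConstructionError(f"pooling ({p},{s}) exhausts {t} samples")
    return out


def closed_form_param_count(spec: ModelSpec) -> dict[str, int]:
    """Per-stage trainable-parameter sums computed purely from the spec
    arithmetic, never from built arrays.  Ends with a ``total`` entry."""
    spec = spec.resolve()
    T, E, u = spec.window_samples, spec.n_channels, spec.head_units
    out: dict[str, int] = {}

    if spec.family == "multits":
        ks = spec.branch_kernels_samples()
        fb, fte = spec.filters_per_branch, spec.fte
        m, fsp, r = spec.feature_multiplier, spec.spatial_filters, spec.se_ratio
        (p1, s1), (p2, s2) = spec.pool_spec
        out["multikernel_temporal"] = fb * sum(ks) + len(ks) * fb + 2 * fte
        if spec.use_se:
            b = max(1, fte // r)
            out["temporal_se"] = fte * b + b * fte
        out["depthwise_spatial"] = fte * m * E + fte * m + 2 * fte * m
        out["pointwise"] = fte * m * fsp + fsp + 2 * fsp
        if spec.use_se:
            b = max(1, fsp // r)
            out["spatial_se"] = fsp * b + b * fsp
        t2 = _pool_len(_pool_len(T, p1, s1), p2, s2)
        out["classifier"] = fsp * t2 * u + u

    elif spec.family == "deep":
        kl = ms_to_samples(spec.stage_kernel_ms, spec.fs)
        fs_ = spec.spatial_filters
        pools = list(spec.pool_spec)
        if spec.reformed:
            ks = spec.branch_kernels_samples()
            fb, fte = spec.filters_per_branch, spec.fte
            out["multikernel_temporal"] = (fb * sum(ks) + len(ks) * fb
                                           + 2 * fte)
            t = T
        else:
            k1 = ms_to_samples(spec.temporal_kernel_ms, spec.fs)
            fte = spec.temporal_filters
            out["temporal_conv"] = fte * k1 + fte + 2 * fte
            t = T - k1 + 1
        out["spatial_conv"] = fs_ * fte * E + fs_ + 2 * fs_
        t = _pool_len(t, *pools[0])
        prev = fs_
        for i, (f, (p, s)) in enumerate(
                zip((2 * fs_, 4 * fs_, 8 * fs_), pools[1:]), start=2):
            out[f"conv_block_{i}"] = f * prev * kl + f + 2 * f
            t = _pool_len(t - kl + 1, p, s)
            prev = f
        out["classifier"] = prev * t * u + u

    elif spec.family == "shallow":
        fs_ = spec.spatial_filters
        (p, s), = spec.pool_spec
        if spec.reformed:
            ks = spec.branch_kernels_samples()
            fb, fte = spec.filters_per_branch, spec.fte
            out["multikernel_temporal"] = (fb * sum(ks) + len(ks) * fb
                                           + 2 * fte)
            t = T
        else:
            k1 = ms_to_samples(spec.temporal_kernel_ms, spec.fs)
            fte = spec.temporal_filters
            out["temporal_conv"] = fte * k1 + fte + 2 * fte
            t = T - k1 + 1
        out["spatial_conv"] = fs_ * fte * E + fs_ + 2 * fs_
        t = _pool_len(t, p, s)
        out["classifier"] = fs_ * t * u + u

    else:  # eegnet
        q = ms_to_samples(spec.sep_kernel_ms, spec.fs)
        m, f2 = spec.feature_multiplier, spec.spatial_filters
        (p1, s1), (p2, s2) = spec.pool_spec
        if spec.reformed:
            ks = spec.branch_kernels_samples()
            fb, fte = spec.filters_per_branch, spec.fte
            out["multikernel_temporal"] = fb * sum(ks) + len(ks) * fb
            pw_bias = 0
        else:
            k1 = ms_to_samples(spec.temporal_kernel_ms, spec.fs)
            fte = spec.temporal_filters
            out["temporal_conv"] = fte * k1 + fte + 2 * fte
            pw_bias = 1
        dw = fte * m
        out["depthwise_spatial"] = dw * E + dw + 2 * dw
        out["separable"] = q * dw + dw * f2 + pw_bias * f2 + 2 * f2
        t = _pool_len(_pool_len(T, p1, s1), p2, s2)
        out["classifier"] = f2 * t * u + u

    out["total"] = sum(out.values())
    return out
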