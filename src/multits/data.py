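"""EEG containers, epoching, EDF import, an epoch store and the synthetic
labelled-EEG generator.

The synthetic generator emulates the structure of epoched emotion-EEG
corpora: each 2 s epoch is a sum of band-limited oscillations (theta, alpha,
beta, gamma) whose amplitudes depend on the class label, weighted by a
band-specific spatial topography across electrodes (with hemispheric
asymmetry for alpha and gamma), on top of 1/f background noise.  Per-subject
amplitude multipliers create the distribution shift that makes
subject-independent evaluation harder than subject-dependent evaluation.
All randomness derives from the config seed, so a config is a complete
description of a dataset.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    ConfigError, EmptyEpochSetError, FormatError, IntegrityError,
    ParameterError, UnsupportedDialectError,
)

__all__ = [
    "Recording", "EpochSet", "SynthConfig", "BAND_EDGES", "BAND_NAMES",
    "load_edf", "epoch_recording", "generate_synthetic_dataset",
    "save_epoch_store", "load_epoch_store", "binarize_rating", "drop_neutral",
    "default_topography", "alpha_contrast_config", "dual_band_config",
    "null_config",
]

# Canonical EEG frequency bands, half-open [lo, hi) Hz.  The printed integer
# ranges (theta 4-7, alpha 8-12, beta 13-32, gamma >32) are realised as
# half-open intervals so adjacent bands never double-count a frequency bin;
# gamma's upper edge is capped at 45 Hz.
BAND_NAMES = ("theta", "alpha", "beta", "gamma")
BAND_EDGES = ((4.0, 8.0), (8.0, 13.0), (13.0, 33.0), (33.0, 45.0))


@dataclass
class Recording:
    """Continuous multi-channel EEG: ``signal`` is (channels, samples) in µV."""

    signal: np.ndarray
    fs: float
    channel_names: Sequence[str]
    subject_id: str = "unknown"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ParameterError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ParameterError("channel_names length must match signal rows")
        if len(self.channel_names) < 1:
            raise ParameterError("at least one channel required")
        if not np.all(np.isfinite(self.signal)):
            raise ParameterError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length labelled windows: ``epochs`` is (n, channels, samples) µV."""

    epochs: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    fs: float
    window_s: float
    channel_names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.epochs.ndim != 3:
            raise ParameterError("epochs must be 3-D (n x channels x samples)")
        n = self.epochs.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ParameterError("labels/subject_ids must match epoch count")
        expected = int(round(self.window_s * self.fs))
        if n and self.epochs.shape[2] != expected:
            raise ParameterError(
                f"window of {self.window_s} s at {self.fs} Hz implies "
                f"{expected} samples, got {self.epochs.shape[2]}")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.epochs.shape[1])]

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def window_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def label_set(self) -> list:
        return sorted(set(self.labels.tolist()))

    def subset(self, idx) -> "EpochSet":
        return EpochSet(self.epochs[idx], self.labels[idx],
                        self.subject_ids[idx], self.fs, self.window_s,
                        self.channel_names)

    @staticmethod
    def concatenate(sets: Sequence["EpochSet"]) -> "EpochSet":
        first = sets[0]
        return EpochSet(
            np.concatenate([s.epochs for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.subject_ids for s in sets]),
            first.fs, first.window_s, first.channel_names)


# ---------------------------------------------------------------------------
# EDF import
# ---------------------------------------------------------------------------

def _edf_header_sampling_check(path: Path):
    """Light header parse: magic bytes and per-channel record sizes.

    Mixed per-channel sampling rates are a legal EDF dialect we do not
    support (every channel must share one rate)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256 or not head[:8].strip().startswith(b"0"):
            raise FormatError(f"{path} is not an EDF file (bad header magic)")
        try:
            ns = int(head[252:256].decode().strip())
        except ValueError as exc:
            raise FormatError(f"{path}: unreadable EDF header") from exc
        fh.seek(256 + ns * 216)
        raw = fh.read(ns * 8)
        if len(raw) < ns * 8:
            raise FormatError(f"{path}: truncated EDF signal headers")
        samples_per_record = {int(raw[i * 8:(i + 1) * 8].decode().strip())
                              for i in range(ns)}
    if len(samples_per_record) > 1:
        raise UnsupportedDialectError(
            f"{path}: channels use different sampling rates "
            f"({sorted(samples_per_record)} samples/record)")


def load_edf(path) -> Recording:
    """Read a European Data Format file into a :class:`Recording` (µV)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _edf_header_sampling_check(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc
    signal = raw.get_data() * 1e6  # mne returns Volts
    if not np.all(np.isfinite(signal)):
        raise FormatError(f"{path}: non-finite samples after import")
    return Recording(signal=signal, fs=float(raw.info["sfreq"]),
                     channel_names=list(raw.ch_names),
                     subject_id=path.stem)


# ---------------------------------------------------------------------------
# epoching and label utilities
# ---------------------------------------------------------------------------

def epoch_recording(rec: Recording, window_s: float, stride_s=None,
                    label="unlabelled") -> EpochSet:
    """Cut a recording into fixed windows tiling from t=0.

    Default stride equals the window (non-overlapping); a trailing partial
    window is discarded.  All epochs inherit ``label`` and the recording's
    subject id.
    """
    if stride_s is None:
        stride_s = window_s
    win = int(round(window_s * rec.fs))
    stride = int(round(stride_s * rec.fs))
    if win < 1:
        raise ParameterError("window_s x fs must be >= 1 sample")
    if stride < 1:
        raise ParameterError("stride_s must be positive")
    if rec.n_samples < win:
        raise EmptyEpochSetError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{win}-sample window")
    n = (rec.n_samples - win) // stride + 1
    starts = np.arange(n) * stride
    epochs = np.stack([rec.signal[:, s:s + win] for s in starts])
    return EpochSet(epochs=epochs,
                    labels=np.array([label] * n, dtype=object),
                    subject_ids=np.array([rec.subject_id] * n, dtype=object),
                    fs=rec.fs, window_s=window_s,
                    channel_names=list(rec.channel_names))


def binarize_rating(rating: float) -> str:
    """Map a 1-9 affective rating to ``negative`` (< 5) or ``positive``."""
    if not 1 <= rating <= 9:
        raise ParameterError(f"rating {rating} outside [1, 9]")
    return "negative" if rating < 5 else "positive"


def drop_neutral(es: EpochSet) -> EpochSet:
    """Remove epochs labelled ``neutral``; order of the rest is preserved."""
    keep = np.array([l != "neutral" for l in es.labels], dtype=bool)
    return es.subset(keep)


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

def default_topography(n_channels: int) -> np.ndarray:
    """Smooth per-band channel weights, (4, n_channels) in (0, 1].

    Channels are laid out left-to-right; alpha and gamma get opposite
    hemispheric gradients, theta a frontal-like bump, beta near-uniform.
    """
    x = np.linspace(-1.0, 1.0, n_channels)
    theta = 0.6 + 0.4 * np.exp(-(x ** 2) / 0.5)
    alpha = 0.5 + 0.5 / (1 + np.exp(-3 * x))       # right-weighted
    beta = np.full(n_channels, 0.8)
    gamma = 0.5 + 0.5 / (1 + np.exp(3 * x))        # left-weighted
    return np.stack([theta, alpha, beta, gamma])


@dataclass
class SynthConfig:
    """Conditions for one synthetic labelled-EEG dataset.

    ``class_band_amplitude`` is (n_classes, 4) oscillation amplitudes in µV
    for theta/alpha/beta/gamma; class names default to ``class0``.. or
    ``negative``/``positive`` for two classes.
    """

    class_band_amplitude: np.ndarray
    n_subjects: int = 4
    epochs_per_class_per_subject: int = 50
    fs: float = 100.0
    n_channels: int = 4
    window_s: float = 2.0
    band_edges: Sequence = BAND_EDGES
    topography: Optional[np.ndarray] = None
    noise_exponent: float = 1.0
    noise_scale: float = 10.0
    subject_jitter: float = 0.1
    class_names: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self):
        self.class_band_amplitude = np.atleast_2d(
            np.asarray(self.class_band_amplitude, dtype=float))
        if self.class_band_amplitude.shape[1] != len(self.band_edges):
            raise ConfigError("class_band_amplitude must have one column per band")
        if np.any(self.class_band_amplitude < 0):
            raise ConfigError("amplitudes must be >= 0")
        nyq = self.fs / 2
        prev_hi = 0.0
        for lo, hi in self.band_edges:
            if not (0 < lo < hi):
                raise ConfigError(f"invalid band ({lo}, {hi})")
            if lo < prev_hi:
                raise ConfigError("band_edges must be non-overlapping/ascending")
            prev_hi = hi
            if (lo + hi) / 2 >= nyq:
                raise ConfigError(
                    f"band centre of ({lo}, {hi}) Hz at or above the "
                    f"Nyquist frequency {nyq} Hz")
        if self.class_names is None:
            ncls = self.class_band_amplitude.shape[0]
            self.class_names = (["negative", "positive"] if ncls == 2 else
                                [f"class{i}" for i in range(ncls)])
        if self.topography is None:
            self.topography = default_topography(self.n_channels)
        self.topography = np.asarray(self.topography, dtype=float)
        if self.topography.shape != (len(self.band_edges), self.n_channels):
            raise ConfigError("topography must be (n_bands, n_channels)")

    @property
    def n_classes(self) -> int:
        return self.class_band_amplitude.shape[0]

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.fs))


def _pink_noise(rng, n_epochs, n_channels, n_samples, fs, exponent, scale):
    """1/f^exponent noise via spectral shaping, unit-free scale in µV RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    white = rng.standard_normal((n_epochs, n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1) * shaping
    noise = np.fft.irfft(spec, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(noise ** 2)) or 1.0
    return noise * (scale / rms)


def generate_synthetic_dataset(cfg: SynthConfig) -> EpochSet:
    """Draw a labelled epoch set from the generative model described in the
    module docstring.  Output is a pure function of ``cfg`` (bit-identical
    across calls for the same seed); labels are balanced per subject."""
    rng = np.random.default_rng(cfg.seed)
    W = cfg.window_samples
    t = np.arange(W) / cfg.fs
    n_bands = len(cfg.band_edges)
    epochs, labels, subjects = [], [], []
    for s in range(cfg.n_subjects):
        # per-subject, per-band multiplicative gain: the distribution shift
        mult = rng.normal(1.0, cfg.subject_jitter, size=n_bands).clip(0.1)
        for c in range(cfg.n_classes):
            n = cfg.epochs_per_class_per_subject
            freqs = np.stack([
                rng.uniform(lo, min(hi, cfg.fs / 2 * 0.95), size=n)
                for (lo, hi) in cfg.band_edges], axis=1)          # (n, bands)
            phases = rng.uniform(0, 2 * np.pi, size=(n, n_bands))
            osc = np.sin(2 * np.pi * freqs[:, :, None] * t
                         + phases[:, :, None])                     # (n, b, W)
            amp = cfg.class_band_amplitude[c] * mult               # (bands,)
            sig = np.einsum("b,be,nbw->new", amp, cfg.topography, osc)
            sig += _pink_noise(rng, n, cfg.n_channels, W, cfg.fs,
                               cfg.noise_exponent, cfg.noise_scale)
            epochs.append(sig)
            labels.extend([cfg.class_names[c]] * n)
            subjects.extend([f"S{s:02d}"] * n)
    return EpochSet(np.concatenate(epochs).astype(np.float32),
                    np.array(labels, dtype=object),
                    np.array(subjects, dtype=object),
                    cfg.fs, cfg.window_s)


def alpha_contrast_config(seed=0, **overrides) -> SynthConfig:
    """Two classes separated by a doubled alpha amplitude."""
    kw = dict(class_band_amplitude=[[2.0, 5.0, 2.0, 1.0],
                                    [2.0, 10.0, 2.0, 1.0]], seed=seed)
    kw.update(overrides)
    return SynthConfig(**kw)


def dual_band_config(seed=0, **overrides) -> SynthConfig:
    """Class signal split between a slow (theta-edge, ~5 Hz) and a fast
    (gamma, ~35 Hz) component; neither band alone separates as well."""
    kw = dict(class_band_amplitude=[[5.0, 2.0, 2.0, 2.0],
                                    [8.0, 2.0, 2.0, 5.0]],
              band_edges=((4.0, 6.0), (8.0, 13.0), (13.0, 33.0),
                          (34.0, 36.0)),
              seed=seed)
    kw.update(overrides)
    return SynthConfig(**kw)


def null_config(seed=0, **overrides) -> SynthConfig:
    """No class contrast: identical amplitude rows (chance-level data)."""
    kw = dict(class_band_amplitude=[[2.0, 5.0, 2.0, 1.0],
                                    [2.0, 5.0, 2.0, 1.0]], seed=seed)
    kw.update(overrides)
    return SynthConfig(**kw)


# ---------------------------------------------------------------------------
# epoch store: manifest.json + little-endian float32 blob
# ---------------------------------------------------------------------------

_STORE_VERSION = 1


def save_epoch_store(es: EpochSet, directory) -> Path:
    """Write an epoch set as ``manifest.json`` plus ``epochs.bin``
    (little-endian float32, C order).  Returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    blob = np.ascontiguousarray(es.epochs, dtype="<f4").tobytes()
    (directory / "epochs.bin").write_bytes(blob)
    manifest = {
        "format": "multits-epoch-store",
        "version": _STORE_VERSION,
        "fs": es.fs,
        "window_s": es.window_s,
        "shape": list(es.epochs.shape),
        "dtype": "<f4",
        "byte_order": "little",
        "labels": [str(l) for l in es.labels],
        "label_set": [str(l) for l in es.label_set],
        "subject_ids": [str(s) for s in es.subject_ids],
        "channel_names": [str(c) for c in es.channel_names],
        "sha256": hashlib.sha256(blob).hexdigest(),
        "n_bytes": len(blob),
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_epoch_store(directory) -> EpochSet:
    """Read an epoch store, verifying byte length and checksum."""
    directory = Path(directory)
    try:
        manifest = json.loads((directory / "manifest.json").read_text())
    except FileNotFoundError as exc:
        raise FormatError(f"{directory}: no manifest.json") from exc
    except json.JSONDecodeError as exc:
        raise FormatError(f"{directory}: unparseable manifest") from exc
    if manifest.get("format") != "multits-epoch-store":
        raise FormatError(f"{directory}: not an epoch store")
    blob = (directory / "epochs.bin").read_bytes()
    if len(blob) != manifest["n_bytes"]:
        raise IntegrityError(
            f"{directory}: blob is {len(blob)} bytes, manifest says "
            f"{manifest['n_bytes']}")
    if hashlib.sha256(blob).hexdigest() != manifest["sha256"]:
        raise IntegrityError(f"{directory}: checksum mismatch")
    shape = tuple(manifest["shape"])
    expected = int(np.prod(shape)) * 4
    if len(blob) != expected:
        raise IntegrityError(
            f"{directory}: shape {shape} implies {expected} bytes, "
            f"blob has {len(blob)}")
    epochs = np.frombuffer(blob, dtype="<f4").reshape(shape).copy()
    return EpochSet(epochs=epochs,
                    labels=np.array(manifest["labels"], dtype=object),
                    subject_ids=np.array(manifest["subject_ids"], dtype=object),
                    fs=manifest["fs"], window_s=manifest["window_s"],
                    channel_names=manifest["channel_names"])
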