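"""Welch power spectral density estimation and band-power features.

Band powers over the four canonical bands (theta, alpha, beta, gamma) are
the feature set consumed by the non-convolutional baselines: one value per
channel per band, flattened channel-major.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .data import BAND_EDGES, BAND_NAMES, EpochSet
from .exceptions import ParameterError

__all__ = ["PsdEstimate", "BandPowerFeatures", "welch_psd", "band_power",
           "extract_band_features"]


@dataclass
class PsdEstimate:
    """One-sided PSD: ``power`` is (channels, freqs) in µV²/Hz."""

    freqs: np.ndarray
    power: np.ndarray
    fs: float
    segment_s: float
    overlap_frac: float


@dataclass
class BandPowerFeatures:
    """Band-power matrix: ``values`` is (epochs, channels x bands) in µV²."""

    values: np.ndarray
    band_edges: Sequence
    channel_names: Sequence[str]

    @property
    def column_names(self) -> list[str]:
        return [f"{ch}_{band}" for ch in self.channel_names
                for band in BAND_NAMES[:len(self.band_edges)]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


def welch_psd(epoch: np.ndarray, fs: float, segment_s: float = 1.0,
              overlap_frac: float = 0.5) -> PsdEstimate:
    """Welch PSD of one epoch (channels x samples), Hann taper, density
    scaling (integrating over frequency approximates the signal variance)."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    nperseg = int(round(segment_s * fs))
    if nperseg < 8:
        raise ParameterError("segment_s x fs must be >= 8 samples")
    if not 0 <= overlap_frac < 1:
        raise ParameterError("overlap_frac must be in [0, 1)")
    if epoch.shape[-1] < nperseg:
        raise ParameterError(
            f"epoch of {epoch.shape[-1]} samples shorter than one "
            f"{nperseg}-sample segment")
    freqs, power = sps.welch(epoch, fs=fs, window="hann", nperseg=nperseg,
                             noverlap=int(round(overlap_frac * nperseg)),
                             detrend=False, scaling="density", axis=-1)
    return PsdEstimate(freqs=freqs, power=power, fs=fs,
                       segment_s=segment_s, overlap_frac=overlap_frac)


def band_power(psd: PsdEstimate, band) -> np.ndarray:
    """Integrated density over ``[lo, hi)`` Hz per channel (trapezoidal).

    Gamma-style open upper edges should already be capped (45 Hz default);
    ``hi`` may not exceed the Nyquist frequency.
    """
    lo, hi = band
    nyq = psd.fs / 2
    if not (0 <= lo < hi <= nyq + 1e-9):
        raise ParameterError(f"band ({lo}, {hi}) invalid for Nyquist {nyq}")
    mask = (psd.freqs >= lo) & (psd.freqs < hi)
    if not np.any(mask):
        raise ParameterError(f"no frequency bins inside [{lo}, {hi}) Hz")
    sub_f = psd.freqs[mask]
    sub_p = psd.power[..., mask]
    if sub_f.size == 1:
        df = psd.freqs[1] - psd.freqs[0]
        return sub_p[..., 0] * df
    return np.trapezoid(sub_p, sub_f, axis=-1)


def extract_band_features(es: EpochSet, segment_s: float = 1.0,
                          overlap_frac: float = 0.5,
                          band_edges=None, log10: bool = False
                          ) -> BandPowerFeatures:
    """Per-epoch, per-channel band powers, flattened channel-major.

    With the default four bands a 62-channel set yields 248 columns.  Bands
    whose lower edge reaches the Nyquist frequency are rejected; cap the
    gamma edge or lower the band set explicitly for low sampling rates.
    """
    band_edges = tuple(band_edges if band_edges is not None else BAND_EDGES)
    nyq = es.fs / 2
    bands = []
    for lo, hi in band_edges:
        if lo >= nyq:
            raise ParameterError(
                f"band ({lo}, {hi}) Hz not representable at fs={es.fs}")
        bands.append((lo, min(hi, nyq)))
    nperseg = int(round(segment_s * es.fs))
    freqs, power = sps.welch(es.epochs.astype(float), fs=es.fs, window="hann",
                             nperseg=nperseg,
                             noverlap=int(round(overlap_frac * nperseg)),
                             detrend=False, scaling="density", axis=-1)
    cols = []
    for b, (lo, hi) in enumerate(bands):
        mask = (freqs >= lo) & (freqs < hi)
        if not np.any(mask):
            raise ParameterError(f"no bins inside [{lo}, {hi}) Hz")
        if mask.sum() == 1:
            bp = power[..., mask][..., 0] * (freqs[1] - freqs[0])
        else:
            bp = np.trapezoid(power[..., mask], freqs[mask], axis=-1)
        cols.append(bp)                       # (epochs, channels)
    stacked = np.stack(cols, axis=-1)         # (epochs, channels, bands)
    values = stacked.reshape(len(es), -1)     # channel-major flatten
    if log10:
        values = np.log10(np.maximum(values, 1e-12))
    return BandPowerFeatures(values=values, band_edges=band_edges,
                             channel_names=list(es.channel_names))
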