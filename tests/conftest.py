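"""Shared fixtures: synthetic datasets at test scale and a minimal EDF
writer used to build import fixtures on the fly (synthetic stand-ins; no
real recordings ship with the package)."""

from __future__ import annotations

import numpy as np
import pytest

from multits.data import SynthConfig, generate_synthetic_dataset


def write_edf(path, signal, fs, phys_min=-200.0, phys_max=200.0,
              channel_names=None):
    """Write a minimal single-rate EDF file (synthetic fixture writer).

    ``signal`` is (channels, samples) in µV; the duration must be a whole
    number of 1 s records.  Returns the quantisation step in µV.
    """
    signal = np.asarray(signal, dtype=float)
    n_ch, n_samp = signal.shape
    spr = int(round(fs))
    if n_samp % spr:
        raise ValueError("signal length must be a whole number of 1 s records")
    n_rec = n_samp // spr
    names = channel_names or [f"EEG ch{i}" for i in range(n_ch)]
    dig_min, dig_max = -32768, 32767

    def field(text, width):
        return f"{text:<{width}.{width}}".encode("ascii")

    header = b"".join([
        field("0", 8), field("X X X X", 80), field("Startdate 01-JAN-2020", 80),
        field("01.01.20", 8), field("00.00.00", 8),
        field(str(256 * (1 + n_ch)), 8), field("", 44),
        field(str(n_rec), 8), field("1", 8), field(str(n_ch), 4),
    ])
    sig_fields = []
    for width, values in [
            (16, names), (80, [""] * n_ch), (8, ["uV"] * n_ch),
            (8, [repr(phys_min)] * n_ch), (8, [repr(phys_max)] * n_ch),
            (8, [str(dig_min)] * n_ch), (8, [str(dig_max)] * n_ch),
            (80, [""] * n_ch), (8, [str(spr)] * n_ch), (32, [""] * n_ch)]:
        sig_fields += [field(v, width) for v in values]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((signal - phys_min) * scale + dig_min),
                      dig_min, dig_max).astype("<i2")
    records = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(sig_fields))
        fh.write(records.tobytes())
    return (phys_max - phys_min) / (dig_max - dig_min)


@pytest.fixture(scope="session")
def edf_writer():
    return write_edf


@pytest.fixture(scope="session")
def low_noise_alpha_cfg():
    """Two classes, alpha amplitude doubled, near-noiseless: band-power
    ratios are dominated by the configured oscillations."""
    return SynthConfig(
        class_band_amplitude=[[2.0, 5.0, 2.0, 1.0],
                              [2.0, 10.0, 2.0, 1.0]],
        noise_scale=1.0, subject_jitter=0.05, seed=42)


@pytest.fixture(scope="session")
def low_noise_alpha_set(low_noise_alpha_cfg):
    return generate_synthetic_dataset(low_noise_alpha_cfg)


@pytest.fixture(scope="session")
def tiny_null_set():
    """Small no-contrast set for fast harness tests."""
    cfg = SynthConfig(class_band_amplitude=[[2.0, 4.0, 2.0, 1.0],
                                            [2.0, 4.0, 2.0, 1.0]],
                      n_subjects=2, epochs_per_class_per_subject=10,
                      seed=5)
    return generate_synthetic_dataset(cfg)
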