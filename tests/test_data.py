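"""Containers, epoching, label utilities, the epoch store, EDF import and
the synthetic generator."""

import numpy as np
import pytest

from multits.data import (
    BAND_EDGES, EpochSet, Recording, SynthConfig, binarize_rating,
    drop_neutral, epoch_recording, generate_synthetic_dataset, load_edf,
    load_epoch_store, save_epoch_store,
)
from multits.exceptions import (
    ConfigError, EmptyEpochSetError, FormatError, IntegrityError,
    ParameterError, UnsupportedDialectError,
)
from multits.spectral import band_power, welch_psd


def _recording(duration_s, fs, n_ch=2, subject="S0", seed=0):
    rng = np.random.default_rng(seed)
    sig = rng.standard_normal((n_ch, int(duration_s * fs)))
    return Recording(sig, fs, [f"ch{i}" for i in range(n_ch)], subject)


class TestEpoching:
    @pytest.mark.parametrize("dur,fs,win,stride,n_expect,len_expect", [
        (10.0, 200.0, 2.0, 2.0, 5, 400),   # 2 s windows -> 400 samples
        (2.0, 200.0, 2.0, 2.0, 1, 400),    # exactly one window
        (5.0, 200.0, 2.0, 1.0, 4, 400),    # overlapping stride
    ])
    def test_epoch_counts(self, dur, fs, win, stride, n_expect, len_expect):
        es = epoch_recording(_recording(dur, fs), win, stride, label="pos")
        assert len(es) == n_expect
        assert es.window_samples == len_expect
        assert set(es.labels) == {"pos"}
        assert set(es.subject_ids) == {"S0"}

    def test_too_short_recording_raises(self):
        with pytest.raises(EmptyEpochSetError):
            epoch_recording(_recording(1.0, 200.0), 2.0)

    def test_nonoverlapping_epochs_reproduce_prefix(self):
        rec = _recording(7.3, 100.0)
        es = epoch_recording(rec, 2.0)
        assert len(es) * es.window_samples <= rec.n_samples
        rebuilt = np.concatenate(list(es.epochs), axis=1)
        np.testing.assert_allclose(
            rebuilt, rec.signal[:, :rebuilt.shape[1]], rtol=0, atol=1e-6)

    def test_non_finite_signal_rejected(self):
        sig = np.zeros((1, 100))
        sig[0, 3] = np.nan
        with pytest.raises(ParameterError):
            Recording(sig, 100.0, ["ch0"])


class TestLabels:
    @pytest.mark.parametrize("rating,expected", [
        (3, "negative"), (5, "positive"), (4.5, "negative"),
        (1, "negative"), (9, "positive"),
    ])
    def test_binarize_rating(self, rating, expected):
        assert binarize_rating(rating) == expected

    @pytest.mark.parametrize("rating", [0, 9.5, -1])
    def test_binarize_out_of_range(self, rating):
        with pytest.raises(ParameterError):
            binarize_rating(rating)

    def test_drop_neutral_keeps_order(self):
        es = EpochSet(np.zeros((3, 1, 10)),
                      np.array(["positive", "negative", "neutral"],
                               dtype=object),
                      np.array(["a", "a", "a"], dtype=object),
                      fs=5.0, window_s=2.0)
        out = drop_neutral(es)
        assert list(out.labels) == ["positive", "negative"]

    def test_drop_neutral_all_neutral_gives_empty(self):
        es = EpochSet(np.zeros((2, 1, 10)),
                      np.array(["neutral", "neutral"], dtype=object),
                      np.array(["a", "a"], dtype=object), 5.0, 2.0)
        assert len(drop_neutral(es)) == 0

    def test_drop_neutral_balanced_three_class(self):
        # a balanced 3-class set of 90 keeps two thirds of the epochs
        labels = np.array(["positive", "neutral", "negative"] * 30,
                          dtype=object)
        es = EpochSet(np.zeros((90, 1, 10)), labels,
                      np.array(["a"] * 90, dtype=object), 5.0, 2.0)
        assert len(drop_neutral(es)) == 60


class TestEpochStore:
    def test_round_trip(self, tmp_path, tiny_null_set):
        save_epoch_store(tiny_null_set, tmp_path / "store")
        back = load_epoch_store(tmp_path / "store")
        np.testing.assert_array_equal(back.epochs, tiny_null_set.epochs)
        assert list(back.labels) == list(tiny_null_set.labels)
        assert list(back.subject_ids) == list(tiny_null_set.subject_ids)
        assert back.fs == tiny_null_set.fs
        assert back.window_s == tiny_null_set.window_s

    def test_tampered_blob_rejected(self, tmp_path, tiny_null_set):
        save_epoch_store(tiny_null_set, tmp_path / "store")
        blob = (tmp_path / "store" / "epochs.bin").read_bytes()
        (tmp_path / "store" / "epochs.bin").write_bytes(blob[:-4])
        with pytest.raises(IntegrityError):
            load_epoch_store(tmp_path / "store")

    def test_corrupted_content_rejected(self, tmp_path, tiny_null_set):
        save_epoch_store(tiny_null_set, tmp_path / "store")
        blob = bytearray((tmp_path / "store" / "epochs.bin").read_bytes())
        blob[10] ^= 0xFF
        (tmp_path / "store" / "epochs.bin").write_bytes(bytes(blob))
        with pytest.raises(IntegrityError):
            load_epoch_store(tmp_path / "store")

    def test_store_is_deterministic_on_disk(self, tmp_path, tiny_null_set):
        save_epoch_store(tiny_null_set, tmp_path / "a")
        save_epoch_store(tiny_null_set, tmp_path / "b")
        assert (tmp_path / "a" / "epochs.bin").read_bytes() == \
            (tmp_path / "b" / "epochs.bin").read_bytes()

    def test_missing_manifest(self, tmp_path):
        with pytest.raises(FormatError):
            load_epoch_store(tmp_path)


class TestEdfImport:
    def test_round_trip_shape_and_fs(self, tmp_path, edf_writer):
        rng = np.random.default_rng(3)
        sig = rng.uniform(-100, 100, size=(2, 2000))
        edf_writer(tmp_path / "a.edf", sig, fs=200)
        rec = load_edf(tmp_path / "a.edf")
        assert rec.signal.shape == (2, 2000)
        assert rec.fs == 200.0
        assert rec.n_channels == 2

    def test_known_sine_within_quantisation(self, tmp_path, edf_writer):
        t = np.arange(1000) / 100.0
        sine = 50.0 * np.sin(2 * np.pi * 7.0 * t)[None, :]
        step = edf_writer(tmp_path / "s.edf", sine, fs=100)
        rec = load_edf(tmp_path / "s.edf")
        assert np.max(np.abs(rec.signal - sine)) <= step

    def test_bad_magic_rejected(self, tmp_path):
        (tmp_path / "bad.edf").write_bytes(b"not an edf at all")
        with pytest.raises(FormatError):
            load_edf(tmp_path / "bad.edf")

    def test_mixed_sampling_rates_unsupported(self, tmp_path, edf_writer):
        edf_writer(tmp_path / "m.edf", np.zeros((2, 200)), fs=100)
        raw = bytearray((tmp_path / "m.edf").read_bytes())
        # per-signal samples/record live after the 216-byte field block
        off = 256 + 2 * 216
        raw[off + 8:off + 16] = b"50      "
        (tmp_path / "m.edf").write_bytes(bytes(raw))
        with pytest.raises(UnsupportedDialectError):
            load_edf(tmp_path / "m.edf")


def _mean_alpha_power(es, labels_value):
    mask = es.labels == labels_value
    powers = []
    for ep in es.epochs[mask]:
        psd = welch_psd(ep, es.fs)
        powers.append(band_power(psd, BAND_EDGES[1]).mean())
    return float(np.mean(powers))


class TestSyntheticGenerator:
    def test_seeded_determinism(self, low_noise_alpha_cfg):
        a = generate_synthetic_dataset(low_noise_alpha_cfg)
        b = generate_synthetic_dataset(low_noise_alpha_cfg)
        assert np.array_equal(a.epochs, b.epochs)
        assert list(a.labels) == list(b.labels)

    def test_labels_balanced_per_subject(self, low_noise_alpha_set):
        es = low_noise_alpha_set
        for s in set(es.subject_ids):
            labs = es.labels[es.subject_ids == s]
            counts = {l: int(np.sum(labs == l)) for l in set(labs)}
            assert len(set(counts.values())) == 1

    def test_null_config_has_no_alpha_contrast(self, tiny_null_set):
        cfg = SynthConfig(class_band_amplitude=[[2.0, 5.0, 2.0, 1.0],
                                                [2.0, 5.0, 2.0, 1.0]],
                          seed=9)
        es = generate_synthetic_dataset(cfg)
        p0 = _mean_alpha_power(es, es.label_set[0])
        p1 = _mean_alpha_power(es, es.label_set[1])
        assert abs(p1 - p0) / p0 < 0.05

    def test_doubled_alpha_amplitude_quadruples_power(
            self, low_noise_alpha_set):
        # power scales with amplitude squared: 2x amplitude -> 4x power
        es = low_noise_alpha_set
        p_neg = _mean_alpha_power(es, "negative")
        p_pos = _mean_alpha_power(es, "positive")
        assert p_pos / p_neg == pytest.approx(4.0, rel=0.15)

    def test_single_band_power_concentrates_in_band(self):
        cfg = SynthConfig(class_band_amplitude=[[0.0, 5.0, 0.0, 0.0]],
                          noise_scale=0.0, n_subjects=1,
                          epochs_per_class_per_subject=8, seed=1)
        es = generate_synthetic_dataset(cfg)
        # direct periodogram oracle, no Welch smoothing
        for ep in es.epochs:
            spec = np.abs(np.fft.rfft(ep.astype(float), axis=-1)) ** 2
            freqs = np.fft.rfftfreq(es.window_samples, 1 / es.fs)
            total = spec.sum()
            in_band = spec[:, (freqs >= 7.0) & (freqs < 14.0)].sum()
            assert in_band / total >= 0.95

    def test_band_power_log_ratio_recovered(self):
        # 500 epochs/class with an isolated alpha contrast: the configured
        # log power ratio log(4) is recovered within 3 standard errors
        # (delta-method SE of a log ratio of means)
        cfg = SynthConfig(class_band_amplitude=[[0.0, 5.0, 0.0, 0.0],
                                                [0.0, 10.0, 0.0, 0.0]],
                          epochs_per_class_per_subject=125,
                          noise_scale=0.2, subject_jitter=0.05, seed=17)
        es = generate_synthetic_dataset(cfg)

        def alpha_powers(label):
            mask = es.labels == label
            return np.array([
                band_power(welch_psd(ep, es.fs), BAND_EDGES[1]).mean()
                for ep in es.epochs[mask]])

        p_neg, p_pos = alpha_powers("negative"), alpha_powers("positive")
        est = np.log(p_pos.mean() / p_neg.mean())
        se = np.sqrt(p_pos.var(ddof=1) / (len(p_pos) * p_pos.mean() ** 2)
                     + p_neg.var(ddof=1) / (len(p_neg) * p_neg.mean() ** 2))
        assert abs(est - np.log(4.0)) <= 3 * se

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(class_band_amplitude=[[1.0, 1.0, 1.0, 1.0]],
                        fs=60.0)  # gamma centre above 30 Hz Nyquist
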