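"""Cleaning-chain tests: filter response, referencing, epoching, ICA."""

import dataclasses

import numpy as np
import pytest

from eegvit.preprocess import (
    PreprocessConfig,
    bandpass_filter,
    epoch,
    ica_clean,
    preprocess_recording,
    rereference,
)
from eegvit.synth import Recording


def _recording_from(data, subject="T1", label=0):
    return Recording(subject, label, np.asarray(data, dtype=float))


def _sinusoid_recording(freq_hz, duration=20.0, fs=250.0):
    t = np.arange(int(duration * fs)) / fs
    return _recording_from(np.tile(np.sin(2 * np.pi * freq_hz * t), (8, 1)))


BAND_05_40 = PreprocessConfig(highpass_hz=0.5, lowpass_hz=40.0)


class TestBandpass:
    def test_dc_input_is_suppressed_below_one_percent(self):
        rec = _recording_from(np.full((8, 5000), 3.0))
        out = bandpass_filter(rec, BAND_05_40)
        # steady-state region, away from filtfilt edge transients
        assert np.abs(out.data[:, 1000:-1000]).max() < 0.03

    @pytest.mark.parametrize(
        "freq,lo,hi",
        [(10.0, 0.95, 1.05),   # mid-passband: unity within 5%
         (60.0, 0.0, 0.2)],    # stopband: strong attenuation
    )
    def test_steady_state_gain_matches_frequency_response(self, freq, lo, hi):
        rec = _sinusoid_recording(freq)
        out = bandpass_filter(rec, BAND_05_40)
        steady = out.data[0, 2000:-2000]
        amplitude = steady.max() - steady.min()
        assert lo <= amplitude / 2 <= hi
        # independent oracle: squared Butterworth magnitude (filtfilt = |H|^2)
        from scipy.signal import butter, sosfreqz

        sos = butter(4, [0.5, 40.0], btype="bandpass", fs=250.0, output="sos")
        _, h = sosfreqz(sos, worN=[freq], fs=250.0)
        assert abs(amplitude / 2 - np.abs(h[0]) ** 2) < 0.05

    def test_lowpass_at_or_above_nyquist_rejected(self):
        rec = _sinusoid_recording(10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, PreprocessConfig(lowpass_hz=125.0))

    def test_output_shape_and_metadata_preserved(self, small_recording):
        out = bandpass_filter(small_recording)
        assert out.data.shape == small_recording.data.shape
        assert out.subject_id == small_recording.subject_id
        assert out.label == small_recording.label


class TestRereference:
    def test_values_one_and_three_around_mean_two_become_plus_minus_one(self):
        data = np.full((8, 1), 2.0)  # remaining channels sit at the mean
        data[0, 0], data[1, 0] = 1.0, 3.0
        out = rereference(_recording_from(data))
        assert out.data[0, 0] == -1.0 and out.data[1, 0] == 1.0

    def test_common_offset_is_invisible(self, rng):
        base = rng.normal(0, 1, (8, 50))
        shifted = base + 17.3
        a = rereference(_recording_from(base))
        b = rereference(_recording_from(shifted))
        assert np.allclose(a.data, b.data, atol=1e-12)

    def test_column_means_vanish(self, rng):
        out = rereference(_recording_from(rng.normal(0, 5, (8, 100))))
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9


class TestEpoch:
    def test_ten_seconds_in_two_second_epochs(self, small_recording):
        cfg = PreprocessConfig(epoch_length=2.0)
        epochs = epoch(small_recording, cfg)  # 12 s -> 6 epochs
        assert len(epochs) == 6
        assert all(e.data.shape == (8, 500) for e in epochs)

    def test_trailing_remainder_dropped_and_prefix_reconstructs(self):
        data = np.arange(8 * 2625, dtype=float).reshape(8, 2625)  # 10.5 s
        rec = _recording_from(data)
        epochs = epoch(rec, PreprocessConfig(epoch_length=2.0))
        assert len(epochs) == 5
        joined = np.concatenate([e.data for e in epochs], axis=1)
        assert np.array_equal(joined, data[:, :2500])

    def test_epoch_longer_than_recording_rejected(self, small_recording):
        with pytest.raises(ValueError, match="exceeds"):
            epoch(small_recording, PreprocessConfig(epoch_length=100.0))


class TestIca:
    def _spiky_mixture(self, rng, duration=20.0, fs=250.0):
        """8-channel linear mixture of a 10 Hz sinusoid and a sparse spike
        train (plain kurtosis far above 20), plus faint noise for full rank."""
        n = int(duration * fs)
        t = np.arange(n) / fs
        sin = np.sin(2 * np.pi * 10.0 * t)
        spikes = np.zeros(n)
        idx = rng.choice(n, size=25, replace=False)
        spikes[idx] = rng.normal(0, 10, size=25)
        sources = np.vstack([sin, spikes])
        mixing = rng.normal(0, 1, (8, 2))
        # moderate independent channel noise keeps the mixture full rank so
        # the 8-component unmixing converges
        data = mixing @ sources + rng.normal(0, 0.3, (8, n))
        return _recording_from(data), sources, mixing

    def test_disabled_ica_is_bit_identical_passthrough(self, small_recording):
        cfg = PreprocessConfig(ica_enabled=False)
        out = ica_clean(small_recording, cfg)
        assert out is small_recording

    def test_spike_source_power_reduced_at_least_tenfold(self, rng):
        rec, sources, mixing = self._spiky_mixture(rng)
        cfg = PreprocessConfig(ica_kurtosis_threshold=10.0, ica_max_iter=1000, ica_tol=1e-3)
        cleaned = ica_clean(rec, cfg, seed=0)
        # project onto the known spike mixing column before/after
        w = mixing[:, 1] / np.linalg.norm(mixing[:, 1])
        # remove the sinusoid's contribution along w to isolate spike power
        spike_sig = sources[1] * np.linalg.norm(mixing[:, 1])
        before = np.sum((w @ rec.data - w @ np.outer(mixing[:, 0], sources[0])) ** 2)
        after = np.sum((w @ cleaned.data - w @ np.outer(mixing[:, 0], sources[0])) ** 2)
        assert np.sum(spike_sig**2) > 0
        assert after < before / 10

    def test_sources_recovered_with_high_correlation(self, rng):
        rec, sources, _ = self._spiky_mixture(rng)
        from sklearn.decomposition import FastICA

        est = FastICA(n_components=2, random_state=0, max_iter=1000).fit_transform(rec.data.T).T
        for src in sources:
            corr = max(abs(np.corrcoef(src, e)[0, 1]) for e in est)
            assert corr >= 0.95

    def test_infinite_thresholds_make_ica_an_identity(self, rng):
        rec, _, _ = self._spiky_mixture(rng)
        cfg = PreprocessConfig(
            ica_kurtosis_threshold=np.inf, ica_highfreq_power_threshold=np.inf,
            ica_max_iter=1000, ica_tol=1e-3,
        )
        out = ica_clean(rec, cfg, seed=1)
        scale = np.abs(rec.data).max()
        assert np.abs(out.data - rec.data).max() < 1e-6 * scale

    def test_convergence_failure_returns_input_with_warning(self, caplog, small_recording):
        import logging

        cfg = PreprocessConfig(ica_max_iter=2)
        with caplog.at_level(logging.WARNING, logger="eegvit.preprocess"):
            out = ica_clean(small_recording, cfg, seed=0)
        assert np.array_equal(out.data, small_recording.data)
        assert any("did not converge" in r.message for r in caplog.records)

    def test_too_short_recording_rejected(self):
        rec = _recording_from(np.random.default_rng(0).normal(0, 1, (8, 500)))  # 2 s
        with pytest.raises(ValueError, match="ICA needs"):
            ica_clean(rec, PreprocessConfig())


def test_uncleaned_arm_still_filters_and_rereferences(small_recording):
    out = preprocess_recording(small_recording, ica=False)
    assert out.data.shape == small_recording.data.shape
    assert np.abs(out.data.mean(axis=0)).max() < 1e-9  # re-referenced
    assert not np.array_equal(out.data, small_recording.data)  # filtered
    assert (out.subject_id, out.label) == (small_recording.subject_id, small_recording.label)
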