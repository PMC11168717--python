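"""Filtering, re-referencing, R-peak detection and IBI derivation."""

import numpy as np
import pytest
from scipy import signal as sps

from bhnet import (
    IBISeries,
    RPeakSeries,
    SignalRecord,
    bandpass_filter,
    common_average_reference,
    detect_r_peaks,
    ibi_from_peaks,
)
from bhnet.errors import InsufficientDataError, InvalidBandError, NoPeaksError
from bhnet.preprocess import butter_bandpass_response
from bhnet.synthetic import ScenarioSpec, generate_ecg, generate_rr

from .conftest import sine_record


class TestBandpassFilter:
    def test_stopband_sinusoid_suppressed(self):
        rec = sine_record(0.1, duration=60.0)
        out = bandpass_filter(rec, 0.5, 45.0, order=4)
        mid = out.samples[0][1000:-1000]
        assert np.max(np.abs(mid)) < 0.05

    def test_passband_sinusoid_preserved(self):
        rec = sine_record(10.0, duration=20.0)
        out = bandpass_filter(rec, 0.5, 45.0, order=4)
        mid = out.samples[0][2000:-2000]
        assert abs(np.max(np.abs(mid)) - 1.0) < 0.02

    def test_white_noise_spectrum_matches_analytic_response(self, rng):
        """Output PSD of filtered white noise follows the squared
        Butterworth magnitude response of the zero-phase design."""
        rate, n = 256.0, 2**18
        x = rng.standard_normal(n)
        rec = SignalRecord(samples=x[None], rate=rate, labels=("w",))
        out = bandpass_filter(rec, 0.5, 45.0, order=4)
        freqs, pxx = sps.welch(out.samples[0], fs=rate, nperseg=4096)
        expected = butter_bandpass_response(freqs, 0.5, 45.0, 4, rate) * (1.0 / rate) * 2
        band = (freqs > 2) & (freqs < 40)
        ratio = pxx[band] / expected[band]
        assert abs(np.mean(ratio) - 1.0) < 0.05

    def test_linearity(self, rng):
        rate = 128.0
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        mk = lambda v: SignalRecord(samples=v[None], rate=rate, labels=("c",))
        f = lambda v: bandpass_filter(mk(v), 1.0, 40.0).samples[0]
        lhs = f(2.0 * x + 3.0 * y)
        rhs = 2.0 * f(x) + 3.0 * f(y)
        assert np.allclose(lhs, rhs, rtol=1e-8, atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        rec = sine_record(10.0, rate=64.0)
        with pytest.raises(InvalidBandError):
            bandpass_filter(rec, 0.5, 32.0)

    def test_nonfinite_input_rejected(self):
        rec = sine_record(10.0)
        bad = rec.samples.copy()
        bad[0, 5] = np.nan
        with pytest.raises(ValueError):
            bandpass_filter(SignalRecord(bad, rec.rate, rec.labels), 0.5, 45.0)


class TestCommonAverageReference:
    def test_antisymmetric_pair_unchanged(self, rng):
        a = rng.standard_normal(500)
        rec = SignalRecord(np.stack([a, -a]), 100.0, ("p", "n"))
        out = common_average_reference(rec)
        assert np.allclose(out.samples, rec.samples)

    def test_constant_offset_removed(self, rng):
        x = rng.standard_normal((4, 300))
        rec = SignalRecord(x, 100.0, ("a", "b", "c", "d"))
        shifted = SignalRecord(x + 7.5, 100.0, ("a", "b", "c", "d"))
        assert np.allclose(
            common_average_reference(rec).samples,
            common_average_reference(shifted).samples,
        )

    def test_channel_mean_is_zero(self, rng):
        x = rng.standard_normal((4, 1000))
        out = common_average_reference(SignalRecord(x, 100.0, tuple("abcd")))
        assert np.max(np.abs(out.samples.mean(axis=0))) < 1e-10

    def test_idempotent(self, rng):
        x = rng.standard_normal((5, 200))
        rec = SignalRecord(x, 100.0, tuple("abcde"))
        once = common_average_reference(rec)
        twice = common_average_reference(once)
        assert np.allclose(once.samples, twice.samples)

    def test_ecg_channel_excluded(self, rng):
        x = rng.standard_normal((3, 100))
        rec = SignalRecord(x, 100.0, ("e1", "e2", "ecg"))
        out = common_average_reference(rec, channels=("e1", "e2"))
        assert np.allclose(out.samples[2], x[2])

    def test_unknown_label_rejected(self, rng):
        rec = SignalRecord(rng.standard_normal((2, 50)), 100.0, ("a", "b"))
        with pytest.raises(ValueError):
            common_average_reference(rec, channels=("a", "zz"))


class TestDetectRPeaks:
    def test_known_peaks_recovered(self):
        spec = ScenarioSpec(seed=7, duration=60.0)
        ibi, _ = generate_rr(spec)
        ecg = generate_ecg(ibi, spec, snr_db=10.0)
        peaks = detect_r_peaks(ecg)
        truth = np.concatenate([[ibi.times[0] - ibi.intervals[0]], ibi.times])
        truth = truth[(truth > 0.2) & (truth < ecg.duration - 0.2)]
        tol = 1.5 / ecg.rate
        matched = sum(np.min(np.abs(peaks.times - t)) <= tol for t in truth)
        assert matched / truth.size >= 0.99
        spurious = sum(np.min(np.abs(truth - p)) > tol for p in peaks.times)
        assert spurious == 0

    def test_flat_signal_raises(self):
        rec = SignalRecord(np.zeros((1, 3000)), 256.0, ("ecg",))
        with pytest.raises(NoPeaksError):
            detect_r_peaks(rec)

    def test_short_recording_raises(self, rng):
        rec = SignalRecord(rng.standard_normal((1, 200)), 256.0, ("ecg",))
        with pytest.raises(InsufficientDataError):
            detect_r_peaks(rec)

    def test_rr_outliers_flagged(self):
        """A grossly irregular beat leaves the physiological RR band and is
        reported through the quality flags."""
        spec = ScenarioSpec(seed=3, duration=60.0)
        ibi, _ = generate_rr(spec)
        intervals = ibi.intervals.copy()
        intervals[30] = 2.6  # pathological pause
        long_ibi = IBISeries(intervals=intervals, times=np.cumsum(intervals))
        ecg = generate_ecg(long_ibi, spec, snr_db=20.0)
        peaks = detect_r_peaks(ecg)
        assert not peaks.quality_flags.all()

    def test_recovery_across_seeds(self):
        """Sensitivity and precision >= 0.99 at 10 dB SNR (many seeds)."""
        sens, prec = [], []
        for seed in range(20):
            spec = ScenarioSpec(seed=seed, duration=60.0)
            ibi, _ = generate_rr(spec)
            ecg = generate_ecg(ibi, spec, snr_db=10.0)
            peaks = detect_r_peaks(ecg)
            truth = np.concatenate([[ibi.times[0] - ibi.intervals[0]], ibi.times])
            truth = truth[(truth > 0.2) & (truth < ecg.duration - 0.2)]
            tol = 2.0 / ecg.rate
            tp = sum(np.min(np.abs(peaks.times - t)) <= tol for t in truth)
            sens.append(tp / truth.size)
            prec.append(
                sum(np.min(np.abs(truth - p)) <= tol for p in peaks.times)
                / len(peaks)
            )
        assert np.mean(sens) >= 0.99
        assert np.mean(prec) >= 0.99


class TestIbiFromPeaks:
    def test_uniform_peaks(self):
        peaks = RPeakSeries(times=np.array([1.0, 2.0, 3.0, 4.0]), source_rate=256.0)
        ibi = ibi_from_peaks(peaks)
        assert np.allclose(ibi.intervals, [1, 1, 1])
        assert np.allclose(ibi.times, [2, 3, 4])

    def test_irregular_peaks(self):
        peaks = RPeakSeries(times=np.array([0.0, 0.8, 1.9]), source_rate=256.0)
        ibi = ibi_from_peaks(peaks)
        assert np.allclose(ibi.intervals, [0.8, 1.1])

    def test_matches_naive_loop(self, rng):
        times = np.sort(rng.uniform(0, 100, 100))
        times += np.arange(100) * 0.3  # enforce strict increase
        ibi = ibi_from_peaks(RPeakSeries(times=times, source_rate=256.0))
        naive = [times[i + 1] - times[i] for i in range(len(times) - 1)]
        assert np.allclose(ibi.intervals, naive)

    def test_roundtrip_through_cumsum(self, rng):
        intervals = rng.uniform(0.5, 1.5, 50)
        times = np.cumsum(intervals) + 10.0
        full = np.concatenate([[10.0], times])
        ibi = ibi_from_peaks(RPeakSeries(times=full, source_rate=256.0))
        assert np.array_equal(ibi.intervals, np.diff(full))

    def test_too_few_peaks(self):
        with pytest.raises(InsufficientDataError):
            ibi_from_peaks(RPeakSeries(times=np.array([0.0, 1.0]), source_rate=256.0))
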