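"""Raw EEG/ECG conditioning and heartbeat extraction.

Covers zero-phase Butterworth band-pass filtering, common-average
re-referencing, template-based R-peak detection on single-lead ECG, and
derivation of the interbeat-interval (IBI) series that all cardiac
computations consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import (
    DataError,
    InsufficientDataError,
    InvalidBandError,
    NoPeaksError,
)

__all__ = [
    "SignalRecord",
    "RPeakSeries",
    "IBISeries",
    "bandpass_filter",
    "common_average_reference",
    "detect_r_peaks",
    "ibi_from_peaks",
]

#: Physiological RR-interval band (seconds) used for quality flagging.
RR_BAND = (0.3, 2.0)


@dataclass(frozen=True)
class SignalRecord:
    """Multichannel biosignal: ``samples`` is channels x time.

    Amplitudes are in microvolts for EEG and millivolts for ECG; ``rate`` is
    the sampling frequency in Hz and ``start_time`` an offset in seconds.
    """

    samples: np.ndarray
    rate: float
    labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self):
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if samples.shape[0] != len(self.labels):
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def pick(self, labels) -> "SignalRecord":
        idx = [self.labels.index(l) for l in labels]
        return replace(self, samples=self.samples[idx], labels=tuple(labels))


@dataclass(frozen=True)
class RPeakSeries:
    """Detected heartbeat times (seconds), strictly increasing.

    ``quality_flags[i]`` is True when beat ``i`` is trusted; a False flag
    marks beats whose implied RR interval leaves the physiological band or
    is a local outlier (> 4 MAD from the local median).
    """

    times: np.ndarray
    source_rate: float
    quality_flags: np.ndarray = field(default=None)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("peak times must be strictly increasing")
        flags = self.quality_flags
        if flags is None:
            flags = np.ones(times.size, dtype=bool)
        flags = np.asarray(flags, dtype=bool)
        if flags.size != times.size:
            raise ValueError("one quality flag per peak required")
        object.__setattr__(self, "quality_flags", flags)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class IBISeries:
    """Interbeat intervals (s) stamped at the terminating beat's time."""

    intervals: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        intervals = np.asarray(self.intervals, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        object.__setattr__(self, "times", times)
        if intervals.shape != times.shape:
            raise ValueError("intervals and times must align")
        if intervals.size and np.any(intervals <= 0):
            raise ValueError("intervals must be positive")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - (self.times[0] - self.intervals[0]))


def bandpass_filter(
    rec: SignalRecord, low: float, high: float, order: int = 4
) -> SignalRecord:
    """Zero-phase Butterworth band-pass (applied forward-backward).

    The effective magnitude response is the squared Butterworth response of
    the given ``order``; phase distortion is zero, which keeps heartbeat- and
    window-locked timing intact.
    """
    nyq = rec.rate / 2.0
    if not (0 < low < high):
        raise InvalidBandError(f"invalid band ({low}, {high}) Hz")
    if high >= nyq:
        raise InvalidBandError(
            f"band edge {high} Hz reaches the Nyquist frequency {nyq} Hz"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if not np.all(np.isfinite(rec.samples)):
        raise DataError("input contains non-finite samples")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=-1)
    return replace(rec, samples=filtered)


def butter_bandpass_response(
    freqs: np.ndarray, low: float, high: float, order: int, rate: float
) -> np.ndarray:
    """|H(f)|^2 of the zero-phase filter used by :func:`bandpass_filter`."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs) / rate)
    # forward-backward application squares the magnitude response
    return np.abs(h) ** 2


def common_average_reference(
    rec: SignalRecord, channels=None
) -> SignalRecord:
    """Subtract the instantaneous mean of the selected (EEG) channels.

    Channels outside ``channels`` (e.g. the ECG lead) are excluded from the
    average and left untouched.
    """
    if channels is None:
        channels = rec.labels
    channels = list(channels)
    unknown = set(channels) - set(rec.labels)
    if unknown:
        raise ValueError(f"unknown channel labels: {sorted(unknown)}")
    if len(channels) < 2:
        raise ValueError("common average reference needs >= 2 channels")
    idx = [rec.labels.index(l) for l in channels]
    out = rec.samples.copy()
    out[idx] -= out[idx].mean(axis=0, keepdims=True)
    return replace(rec, samples=out)


def _candidate_peaks(x: np.ndarray, rate: float, refractory: float) -> np.ndarray:
    """Amplitude-threshold candidates with a refractory distance."""
    thr = np.mean(x) + 2.0 * np.std(x)
    dist = max(1, int(round(refractory * rate)))
    peaks, _ = sps.find_peaks(x, height=thr, distance=dist)
    return peaks


def _template_correlate(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of the signal with a beat template."""
    t = template - template.mean()
    tn = np.linalg.norm(t)
    if tn == 0:
        return np.zeros_like(x)
    corr = sps.fftconvolve(x, t[::-1], mode="same")
    # local signal energy for normalization
    win = np.ones(t.size)
    local_sq = sps.fftconvolve(x**2, win, mode="same")
    local_mean = sps.fftconvolve(x, win, mode="same") / t.size
    local_energy = np.sqrt(np.maximum(local_sq - t.size * local_mean**2, 1e-30))
    return corr / (tn * local_energy)


def _flag_rr_outliers(times: np.ndarray) -> np.ndarray:
    """True = trusted beat. Flags RR outside RR_BAND or > 4 MAD from the
    local median (9-beat neighborhood)."""
    flags = np.ones(times.size, dtype=bool)
    if times.size < 3:
        return flags
    rr = np.diff(times)
    bad_rr = (rr < RR_BAND[0]) | (rr > RR_BAND[1])
    half = 4
    for i in range(rr.size):
        lo, hi = max(0, i - half), min(rr.size, i + half + 1)
        nbhd = rr[lo:hi]
        med = np.median(nbhd)
        mad = np.median(np.abs(nbhd - med))
        if mad > 0 and abs(rr[i] - med) > 4.0 * mad:
            bad_rr[i] = True
    # an interval flags the beat that terminates it
    flags[1:] &= ~bad_rr
    return flags


def detect_r_peaks(
    ecg: SignalRecord,
    template_len: float = 0.12,
    refractory: float = 0.3,
) -> RPeakSeries:
    """Template-based R-peak detection on a single-lead ECG.

    A provisional beat template is built as the median waveform around
    amplitude-threshold candidates; the signal is then scanned with the
    normalized template cross-correlation and peaks of the correlation are
    taken as beats (one refinement pass, both polarities tested, refractory
    period enforced). Beats whose implied RR interval leaves the
    physiological band or is a local outlier are flagged, not removed.
    """
    if ecg.n_channels != 1:
        raise ValueError("detect_r_peaks expects a single ECG channel")
    if ecg.duration < 10.0:
        raise InsufficientDataError("ECG shorter than 10 s")
    x = ecg.samples[0].astype(float)
    if not np.all(np.isfinite(x)):
        raise DataError("ECG contains non-finite samples")
    if np.ptp(x) == 0:
        raise NoPeaksError("flat ECG signal")
    rate = ecg.rate

    half = max(2, int(round(template_len * rate / 2)))
    best = None
    for polarity in (+1.0, -1.0):
        y = polarity * x
        cand = _candidate_peaks(y, rate, refractory)
        if cand.size < 3:
            continue
        # median beat template from candidates fully inside the record
        keep = cand[(cand >= half) & (cand < x.size - half)]
        if keep.size < 3:
            continue
        beats = np.stack([y[i - half : i + half + 1] for i in keep])
        template = np.median(beats, axis=0)
        corr = _template_correlate(y, template)
        dist = max(1, int(round(refractory * rate)))
        peaks, props = sps.find_peaks(corr, height=0.5, distance=dist)
        if peaks.size < 3:
            continue
        # refinement pass: rebuild template from matched beats, re-scan
        keep = peaks[(peaks >= half) & (peaks < x.size - half)]
        if keep.size >= 3:
            template = np.median(
                np.stack([y[i - half : i + half + 1] for i in keep]), axis=0
            )
            corr = _template_correlate(y, template)
            peaks, props = sps.find_peaks(corr, height=0.5, distance=dist)
        # snap each correlation peak to the local signal maximum
        snapped = []
        snap = max(1, int(round(0.03 * rate)))
        for p in peaks:
            lo, hi = max(0, p - snap), min(x.size, p + snap + 1)
            snapped.append(lo + int(np.argmax(y[lo:hi])))
        snapped = np.unique(snapped)
        amps = y[snapped]
        # low-amplitude correlation hits are noise, not beats
        keep_amp = amps >= 0.4 * np.median(amps)
        snapped = snapped[keep_amp]
        if snapped.size < 3:
            continue
        # correct polarity gives the larger snapped beat amplitude
        score = float(np.median(y[snapped]))
        if best is None or score > best[0]:
            best = (score, snapped)

    if best is None:
        raise NoPeaksError("no plausible heartbeats found")
    idx = best[1]
    times = ecg.start_time + idx / rate
    flags = _flag_rr_outliers(times)
    return RPeakSeries(times=times, source_rate=rate, quality_flags=flags)


def ibi_from_peaks(peaks: RPeakSeries, use_flags: bool = False) -> IBISeries:
    """First differences of the beat times, stamped at the terminating beat.

    With ``use_flags=True`` beats flagged as untrusted are dropped before
    differencing (the reject branch of misdetection handling).
    """
    times = peaks.times
    if use_flags:
        times = times[peaks.quality_flags]
    if times.size < 3:
        raise InsufficientDataError("need at least 3 beats to form IBIs")
    return IBISeries(intervals=np.diff(times), times=times[1:])
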