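"""Time-varying spectral-coherence connectivity from multichannel EEG.

Per-channel auto spectra and per-pair cross spectra are computed with a
Hann-tapered short-time Fourier transform (default 2-s windows, 50%
overlap). Magnitude-squared-free coherence at window t and frequency f is

    COH_ij[t, f] = |P_ij[f]| / sqrt(P_i[f] * P_j[f])

where the auto/cross spectra are first averaged over a trailing block of
``smooth_K`` windows: single-segment coherence is identically 1, so some
spectral averaging is required for the ratio to be informative. With 2-s
windows at 50% overlap the window centers fall on a 1-s grid, preserving
the 1-s resolution of the downstream network-metric series.

Coherence is then averaged within canonical frequency bands (alpha 8-12,
beta 12-30, gamma 30-45 Hz) to give one weighted connectivity matrix per
band per second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, InvalidBandError
from .preprocess import SignalRecord

__all__ = [
    "SpectralWindowSet",
    "BandGraphSequence",
    "DEFAULT_BANDS",
    "stft_spectra",
    "coherence",
    "band_integrate",
    "band_graph_sequences",
]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass(frozen=True)
class SpectralWindowSet:
    """Windowed auto/cross spectral densities.

    ``auto_spectra`` is (n_channels, n_windows, n_freqs) real, non-negative;
    ``cross_spectra`` is (n_pairs, n_windows, n_freqs) complex for the
    upper-triangle pairs listed in ``pairs``.
    """

    window_times: np.ndarray
    freqs: np.ndarray
    auto_spectra: np.ndarray
    cross_spectra: np.ndarray
    pairs: np.ndarray
    labels: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return self.auto_spectra.shape[0]

    @property
    def n_windows(self) -> int:
        return self.auto_spectra.shape[1]


@dataclass(frozen=True)
class BandGraphSequence:
    """Per-band time-indexed connectivity matrices on a 1-s grid.

    ``weighted`` holds the band-averaged coherence (time, n, n) in [0, 1];
    ``binary`` the sparsified graphs after efficiency-cost optimization,
    with ``density`` the per-time retained edge density. ``binary`` and
    ``density`` are filled by the graph stage.
    """

    band: str
    band_limits: tuple[float, float]
    times: np.ndarray
    weighted: np.ndarray
    labels: tuple[str, ...]
    binary: np.ndarray = None
    density: np.ndarray = None

    @property
    def n_nodes(self) -> int:
        return self.weighted.shape[1]

    def __len__(self) -> int:
        return self.times.size


def stft_spectra(
    rec: SignalRecord, win: float = 2.0, overlap: float = 0.5
) -> SpectralWindowSet:
    """Hann-tapered windowed auto/cross spectral densities.

    Number of windows is ``floor((T - win)/(win*(1-overlap))) + 1``; window
    ``k`` covers samples ``[k*step, k*step + nwin)`` and is stamped at its
    center time.
    """
    nwin = int(round(win * rec.rate))
    if nwin < 4:
        raise ValueError("window too short for the sampling rate")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    if rec.n_samples < nwin:
        raise InsufficientDataError("recording shorter than one window")
    step = max(1, int(round(nwin * (1 - overlap))))
    n_windows = (rec.n_samples - nwin) // step + 1
    taper = sps.get_window("hann", nwin, fftbins=True)
    scale = 1.0 / (rec.rate * np.sum(taper**2))  # density normalization

    starts = np.arange(n_windows) * step
    idx = starts[:, None] + np.arange(nwin)[None, :]
    segments = rec.samples[:, idx] * taper  # (ch, win, nwin)
    spec = np.fft.rfft(segments, axis=-1)  # (ch, win, freq)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / rec.rate)

    n = rec.n_channels
    iu, ju = np.triu_indices(n, k=1)
    auto = (np.abs(spec) ** 2) * scale
    cross = spec[iu] * np.conj(spec[ju]) * scale
    centers = rec.start_time + (starts + (nwin - 1) / 2.0) / rec.rate
    return SpectralWindowSet(
        window_times=centers,
        freqs=freqs,
        auto_spectra=auto,
        cross_spectra=cross,
        pairs=np.column_stack([iu, ju]),
        labels=rec.labels,
    )


def coherence(spec: SpectralWindowSet, smooth_K: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-block coherence tensor.

    Auto and cross spectra are averaged over the ``smooth_K`` windows ending
    at each window index before forming the coherence ratio; the first
    ``smooth_K - 1`` windows are dropped. Returns ``(times, coh)`` with
    ``coh`` of shape (n_windows', n_pairs, n_freqs) in [0, 1].
    """
    if smooth_K < 2:
        raise ValueError(
            "smooth_K must be >= 2: coherence from a single spectral "
            "segment is identically 1"
        )
    if spec.n_windows < smooth_K:
        raise InsufficientDataError("fewer windows than the smoothing block")

    def trail(x):
        # trailing moving average along the window axis
        c = np.cumsum(x, axis=1)
        out = c[:, smooth_K - 1 :] .copy()
        out[:, 1:] -= c[:, :-smooth_K]
        return out / smooth_K

    auto_bar = trail(spec.auto_spectra)
    cross_bar = trail(spec.cross_spectra)
    i, j = spec.pairs[:, 0], spec.pairs[:, 1]
    denom = np.sqrt(auto_bar[i] * auto_bar[j])
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(cross_bar) / denom
    coh = np.nan_to_num(coh, nan=0.0)
    coh = np.clip(coh, 0.0, 1.0)
    times = spec.window_times[smooth_K - 1 :]
    return times, np.moveaxis(coh, 1, 0)


def band_integrate(
    times: np.ndarray,
    coh: np.ndarray,
    freqs: np.ndarray,
    pairs: np.ndarray,
    labels,
    bands: dict[str, tuple[float, float]] = None,
) -> list[BandGraphSequence]:
    """Average coherence over in-band frequency bins, per band and time.

    Band edges are inclusive on both ends; bin membership is by bin center.
    Matrices are symmetrized with a zero diagonal.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    n = len(labels)
    out = []
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs <= hi)
        if not np.any(mask):
            raise InvalidBandError(f"band {name} [{lo}, {hi}] Hz holds no bins")
        band_mean = coh[:, :, mask].mean(axis=2)  # (time, pair)
        mats = np.zeros((times.size, n, n))
        iu, ju = pairs[:, 0], pairs[:, 1]
        mats[:, iu, ju] = band_mean
        mats[:, ju, iu] = band_mean
        out.append(
            BandGraphSequence(
                band=name,
                band_limits=(lo, hi),
                times=np.asarray(times, dtype=float),
                weighted=mats,
                labels=tuple(labels),
            )
        )
    return out


def band_graph_sequences(
    rec: SignalRecord,
    win: float = 2.0,
    overlap: float = 0.5,
    smooth_K: int = 3,
    bands: dict[str, tuple[float, float]] = None,
) -> list[BandGraphSequence]:
    """EEG record -> weighted band graph sequences (full connectivity stage)."""
    spec = stft_spectra(rec, win=win, overlap=overlap)
    times, coh = coherence(spec, smooth_K=smooth_K)
    return band_integrate(times, coh, spec.freqs, spec.pairs, rec.labels, bands)
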