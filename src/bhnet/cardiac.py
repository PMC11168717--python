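"""Poincare-plot descriptors and time-varying cardiac autonomic indices.

The Poincare plot scatters each interbeat interval (IBI) against the next;
the minor/major axes of the fitted ellipse, SD1 and SD2, capture short- and
long-term heart-rate variability. With ``IBI'`` the first difference of the
interval series and ``std`` the sample standard deviation,

    SD01 = sqrt(1/2 * std(IBI')^2)
    SD02 = sqrt(2 * std(IBI)^2 - 1/2 * std(IBI')^2)

are the whole-condition descriptors. Their time-varying counterparts
SD1(t), SD2(t) evaluate the same formulas on the beats inside a trailing
window [t - T, t] (default T = 15 s). The cardiac vagal and sympathetic
index series re-anchor the demeaned fluctuations to the global values:

    CVI(t) = SD01 + (SD1(t) - mean_t SD1)
    CSI(t) = SD02 + (SD2(t) - mean_t SD2)

Fast, beat-to-beat changes (SD1/CVI) are read as vagal activity; slower
drifts (SD2/CSI) as sympathetic activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientDataError
from .preprocess import IBISeries

__all__ = [
    "PoincareDescriptors",
    "CardiacIndexSeries",
    "global_poincare",
    "sliding_poincare",
    "cardiac_indices",
    "cardiac_index_series",
]

#: Minimum number of IBI samples needed to evaluate the descriptors
#: (the sample std of IBI' needs at least two first differences).
MIN_WINDOW_INTERVALS = 3


@dataclass(frozen=True)
class PoincareDescriptors:
    """Whole-condition Poincare ellipse ratios, in seconds."""

    sd01: float
    sd02: float


@dataclass(frozen=True)
class CardiacIndexSeries:
    """CSI(t)/CVI(t) on a uniform grid; NaN marks undefined windows."""

    times: np.ndarray
    csi: np.ndarray
    cvi: np.ndarray
    window_T: float
    sd1: np.ndarray = None
    sd2: np.ndarray = None

    def __post_init__(self):
        for name in ("times", "csi", "cvi", "sd1", "sd2"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        if self.window_T <= 0:
            raise ValueError("window_T must be positive")
        steps = np.diff(self.times)
        if steps.size and not np.allclose(steps, steps[0]):
            raise ValueError("times must be uniformly spaced")

    def __len__(self) -> int:
        return self.times.size


def _poincare_from_intervals(intervals: np.ndarray) -> tuple[float, float]:
    """Evaluate the ellipse-ratio formulas on one interval vector."""
    d = np.diff(intervals)
    var_d = np.var(d, ddof=1)
    var_i = np.var(intervals, ddof=1)
    sd01 = np.sqrt(0.5 * var_d)
    radicand = 2.0 * var_i - 0.5 * var_d
    return float(sd01), float(radicand)


def global_poincare(ibi: IBISeries) -> PoincareDescriptors:
    """Whole-condition SD01/SD02 from the interval series.

    Uses the sample (n-1) standard deviation throughout. Raises
    :class:`DegenerateGeometryError` when the SD02 radicand is negative
    (possible for strongly alternating rhythms).
    """
    if len(ibi) < MIN_WINDOW_INTERVALS:
        raise InsufficientDataError("need >= 3 intervals for Poincare descriptors")
    sd01, radicand = _poincare_from_intervals(ibi.intervals)
    if radicand < 0:
        raise DegenerateGeometryError(radicand)
    return PoincareDescriptors(sd01=sd01, sd02=float(np.sqrt(radicand)))


def sliding_poincare(
    ibi: IBISeries, T: float = 15.0, grid_step: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-varying SD1(t), SD2(t) over trailing windows [t - T, t].

    Returns ``(times, sd1, sd2)`` on a uniform grid with step ``grid_step``
    starting at the first grid point >= first beat time + T. Windows holding
    fewer than three intervals, and windows with a negative SD2 radicand,
    yield NaN.
    """
    if T <= 0:
        raise ValueError("window length T must be positive")
    if len(ibi) == 0:
        raise InsufficientDataError("empty IBI series")
    t0, t1 = float(ibi.times[0]), float(ibi.times[-1])
    if t1 - (t0 - ibi.intervals[0]) < T:
        raise InsufficientDataError("recording shorter than one window")
    start = np.ceil((t0 + T) / grid_step) * grid_step
    grid = np.arange(start, t1 + grid_step / 2, grid_step)
    sd1 = np.full(grid.size, np.nan)
    sd2 = np.full(grid.size, np.nan)
    n_degenerate = 0
    for k, t in enumerate(grid):
        mask = (ibi.times >= t - T) & (ibi.times <= t)
        seg = ibi.intervals[mask]
        if seg.size < MIN_WINDOW_INTERVALS:
            continue
        s1, radicand = _poincare_from_intervals(seg)
        sd1[k] = s1
        if radicand < 0:
            n_degenerate += 1
        else:
            sd2[k] = np.sqrt(radicand)
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} window(s) had a negative SD2 radicand; "
            "marked missing",
            RuntimeWarning,
            stacklevel=2,
        )
    return grid, sd1, sd2


def cardiac_indices(
    times: np.ndarray,
    sd1: np.ndarray,
    sd2: np.ndarray,
    descriptors: PoincareDescriptors,
    window_T: float = 15.0,
) -> CardiacIndexSeries:
    """Re-anchor demeaned SD1(t)/SD2(t) to the global descriptors.

    The mean is taken over the defined grid points of the condition, so
    mean_t CVI = SD01 and mean_t CSI = SD02 by construction.
    """
    sd1 = np.asarray(sd1, dtype=float)
    sd2 = np.asarray(sd2, dtype=float)
    if not (np.any(np.isfinite(sd1)) and np.any(np.isfinite(sd2))):
        raise InsufficientDataError("all sliding descriptors are missing")
    cvi = descriptors.sd01 + (sd1 - np.nanmean(sd1))
    csi = descriptors.sd02 + (sd2 - np.nanmean(sd2))
    return CardiacIndexSeries(
        times=times, csi=csi, cvi=cvi, window_T=window_T, sd1=sd1, sd2=sd2
    )


def cardiac_index_series(
    ibi: IBISeries, T: float = 15.0, grid_step: float = 1.0
) -> CardiacIndexSeries:
    """Full cardiac stage: global + sliding descriptors -> CSI(t), CVI(t)."""
    desc = global_poincare(ibi)
    times, sd1, sd2 = sliding_poincare(ibi, T=T, grid_step=grid_step)
    return cardiac_indices(times, sd1, sd2, desc, window_T=T)
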