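"""Plotting helpers and the visualization-only smoothing utility."""

from __future__ import annotations

import numpy as np

__all__ = ["sliding_mean_smooth", "plot_coupling_table", "plot_metric_and_cardiac"]


def sliding_mean_smooth(values: np.ndarray, window: int = 6) -> np.ndarray:
    """Centered sliding-mean smoothing (default 6 samples = 6 s at the 1-s
    grid). For display only — never part of the analysis path, which
    consumes the unsmoothed series."""
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    half = window // 2
    for i in range(v.size):
        seg = v[max(0, i - half) : i + window - half]
        if np.any(np.isfinite(seg)):
            out[i] = np.nanmean(seg)
    return out


def plot_coupling_table(table, ax=None):
    """Heatmap of MIC values, bands x (metric, cardiac index)."""
    import matplotlib.pyplot as plt

    pivot = table.pivot_table(
        index="band", columns=["metric", "cardiac_index"], values="mic"
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    im = ax.imshow(pivot.to_numpy(), vmin=0, vmax=1, cmap="viridis", aspect="auto")
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_xticks(
        range(len(pivot.columns)),
        [f"{m}\n{c}" for m, c in pivot.columns],
        fontsize=7,
    )
    ax.figure.colorbar(im, ax=ax, label="MIC")
    ax.set_title("Brain network-cardiac coupling")
    return ax


def plot_metric_and_cardiac(
    metric_times, metric_values, cardiac_times, cardiac_values, smooth_window=6, ax=None
):
    """Overlay a (display-smoothed) metric series with a cardiac index."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    sm = sliding_mean_smooth(np.asarray(metric_values, dtype=float), smooth_window)
    ax.plot(metric_times, _zscore(sm), label="network metric (smoothed)")
    ax.plot(cardiac_times, _zscore(np.asarray(cardiac_values, dtype=float)),
            label="cardiac index")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("z-scored amplitude")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def _zscore(v):
    m, s = np.nanmean(v), np.nanstd(v)
    return (v - m) / s if s > 0 else v - m
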