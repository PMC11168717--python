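"""Model/Results facade over the full brain-heart coupling pipeline.

:class:`BrainHeartCoupling` is built from a cleaned multichannel EEG
record plus heartbeat data (an IBI series, R-peaks, or a raw ECG lead);
``fit()`` runs connectivity -> ECO binarization -> metric series and
sliding Poincare -> cardiac index series, estimates the MIC for every
(band x metric x cardiac index) combination, and optionally attaches a
circular-shift permutation null per combination. The returned
:class:`CouplingResults` carries the 24-row coupling table, the
intermediate series, and a printable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cardiac as _cardiac
from . import connectivity as _conn
from . import coupling as _coupling
from . import graph as _graph
from .preprocess import (
    IBISeries,
    RPeakSeries,
    SignalRecord,
    detect_r_peaks,
    ibi_from_peaks,
)

__all__ = ["BrainHeartCoupling", "CouplingResults"]


@dataclass
class CouplingResults:
    """Fitted brain-heart coupling estimates for one recording/condition."""

    table: pd.DataFrame
    metric_series: list
    cardiac_series: object
    band_graphs: list
    params: dict = field(default_factory=dict)
    null_quantile: float = 0.95

    def mic(self, band: str, metric: str, cardiac_index: str) -> float:
        row = self.table[
            (self.table.band == band)
            & (self.table.metric == metric)
            & (self.table.cardiac_index == cardiac_index)
        ]
        if row.empty:
            raise KeyError((band, metric, cardiac_index))
        return float(row.mic.iloc[0])

    def summary(self) -> str:
        lines = [
            "Brain network-cardiac coupling (MIC)",
            "=" * 60,
            f"bands: {sorted(self.table.band.unique())}",
            f"pairs per estimate: {int(self.table.n_pairs.min())}"
            f"-{int(self.table.n_pairs.max())}",
        ]
        for k, v in self.params.items():
            lines.append(f"{k}: {v}")
        lines.append("-" * 60)
        cols = ["band", "metric", "cardiac_index", "mic", "best_grid"]
        if "null_p95" in self.table.columns:
            cols += ["null_p95", "exceeds_null"]
        lines.append(
            self.table[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}")
        )
        return "\n".join(lines)

    def plot(self, **kwargs):
        from .plotting import plot_coupling_table

        return plot_coupling_table(self.table, **kwargs)


class BrainHeartCoupling:
    """Coupling model between EEG network fluctuations and cardiac indices.

    Parameters
    ----------
    eeg:
        Cleaned (filtered, re-referenced, artifact-free) EEG record.
    ibi:
        Interbeat-interval series in seconds.
    bands:
        Mapping band name -> (lo, hi) Hz; defaults to alpha/beta/gamma.
    window_T:
        Trailing Poincare window length in seconds (default 15).
    stft_win, stft_overlap, smooth_K:
        Short-time spectral parameters: window length (s), fractional
        overlap, and the trailing spectral-averaging block for coherence.
    """

    def __init__(
        self,
        eeg: SignalRecord,
        ibi: IBISeries,
        bands: dict | None = None,
        window_T: float = 15.0,
        grid_step: float = 1.0,
        stft_win: float = 2.0,
        stft_overlap: float = 0.5,
        smooth_K: int = 3,
        mic_exponent: float = 0.6,
        clumps_c: int = 15,
    ):
        self.eeg = eeg
        self.ibi = ibi
        self.bands = dict(bands) if bands is not None else dict(_conn.DEFAULT_BANDS)
        self.window_T = window_T
        self.grid_step = grid_step
        self.stft_win = stft_win
        self.stft_overlap = stft_overlap
        self.smooth_K = smooth_K
        self.mic_exponent = mic_exponent
        self.clumps_c = clumps_c

    @classmethod
    def from_signals(
        cls, eeg: SignalRecord, ecg: SignalRecord, use_flags: bool = True, **kwargs
    ) -> "BrainHeartCoupling":
        """Build from a raw ECG lead by running R-peak detection."""
        peaks = detect_r_peaks(ecg)
        return cls(eeg, ibi_from_peaks(peaks, use_flags=use_flags), **kwargs)

    @classmethod
    def from_peaks(cls, eeg: SignalRecord, peaks: RPeakSeries, **kwargs):
        return cls(eeg, ibi_from_peaks(peaks), **kwargs)

    @classmethod
    def from_scenario(cls, scenario, **kwargs) -> "BrainHeartCoupling":
        """Build from a synthetic :class:`~bhnet.synthetic.Scenario`."""
        return cls(scenario.eeg, scenario.ibi, **kwargs)

    def fit(self, seed: int = 0, n_perm: int = 0) -> CouplingResults:
        """Run the full pipeline; with ``n_perm > 0`` attach a circular
        time-shift permutation null (95th percentile) per combination."""
        sequences = _conn.band_graph_sequences(
            self.eeg,
            win=self.stft_win,
            overlap=self.stft_overlap,
            smooth_K=self.smooth_K,
            bands=self.bands,
        )
        metric_series = [
            _graph.metric_time_series(seq, seed=seed) for seq in sequences
        ]
        cardiac = _cardiac.cardiac_index_series(
            self.ibi, T=self.window_T, grid_step=self.grid_step
        )
        table = _coupling.coupling_table(
            metric_series,
            cardiac,
            alpha_exp=self.mic_exponent,
            clumps_c=self.clumps_c,
        )
        if n_perm > 0:
            p95, exceeds = [], []
            rng = np.random.default_rng(seed)
            for _, row in table.iterrows():
                ms = next(m for m in metric_series if m.band == row.band)
                pair = _coupling.align_series(
                    ms.times,
                    ms.values[row.metric].to_numpy(),
                    cardiac.times,
                    getattr(cardiac, row.cardiac_index),
                )
                null = _coupling.mic_null(
                    pair,
                    n_perm=n_perm,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    alpha_exp=self.mic_exponent,
                    clumps_c=self.clumps_c,
                )
                q = float(np.quantile(null, 0.95))
                p95.append(q)
                exceeds.append(bool(row.mic > q))
            table = table.assign(null_p95=p95, exceeds_null=exceeds)
        return CouplingResults(
            table=table,
            metric_series=metric_series,
            cardiac_series=cardiac,
            band_graphs=sequences,
            params={
                "window_T": self.window_T,
                "stft_win": self.stft_win,
                "stft_overlap": self.stft_overlap,
                "smooth_K": self.smooth_K,
                "mic_exponent": self.mic_exponent,
                "seed": seed,
                "n_perm": n_perm,
            },
        )
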