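"""Readers and writers for biosignal files and pipeline outputs.

EDF/BDF recordings are read through MNE (optional dependency); delimited
numeric text (one column per channel with a header row of labels, sampling
rate supplied in a JSON sidecar or argument) and plain-text RR interval
files (one interval in seconds per line) are handled with pandas/numpy.
All pipeline outputs are self-describing tabular text plus a JSON run
manifest recording parameters, seed and package versions.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .cardiac import CardiacIndexSeries
from .graph import MetricSeries
from .preprocess import IBISeries, RPeakSeries, SignalRecord

__all__ = [
    "read_edf",
    "read_delimited",
    "read_rr_text",
    "read_peaks_text",
    "write_record",
    "write_cardiac",
    "write_metrics",
    "write_manifest",
]


def read_edf(path, picks=None) -> SignalRecord:
    """Read an EDF/BDF recording (16/24-bit) via MNE."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF/BDF requires the 'mne' package (install bhnet[edf])"
        ) from exc
    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    if picks is not None:
        raw = raw.pick(picks)
    data = raw.get_data() * 1e6  # volts -> microvolts
    return SignalRecord(
        samples=data, rate=float(raw.info["sfreq"]), labels=tuple(raw.ch_names)
    )


def read_delimited(path, rate: float | None = None, sep=None) -> SignalRecord:
    """Delimited text: header row of channel labels, one column per channel.

    The sampling rate comes from ``rate`` or a JSON sidecar ``<path>.json``
    with a ``"rate"`` entry.
    """
    path = Path(path)
    if rate is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError("sampling rate missing: pass rate= or provide a sidecar")
        rate = float(json.loads(sidecar.read_text())["rate"])
    frame = pd.read_csv(path, sep=sep, engine="python")
    return SignalRecord(
        samples=frame.to_numpy().T, rate=rate, labels=tuple(frame.columns)
    )


def read_rr_text(path) -> IBISeries:
    """Plain-text RR intervals (one value in seconds per line)."""
    intervals = np.loadtxt(path, ndmin=1)
    times = np.cumsum(intervals)
    return IBISeries(intervals=intervals, times=times)


def read_peaks_text(path, source_rate: float = 0.0) -> RPeakSeries:
    """Plain-text R-peak times (one value in seconds per line)."""
    times = np.loadtxt(path, ndmin=1)
    return RPeakSeries(times=times, source_rate=source_rate)


def write_record(rec: SignalRecord, path) -> None:
    path = Path(path)
    frame = pd.DataFrame(rec.samples.T, columns=list(rec.labels))
    frame.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"rate": rec.rate, "start_time": rec.start_time}))


def write_cardiac(series: CardiacIndexSeries, path) -> None:
    pd.DataFrame(
        {
            "time": series.times,
            "SD1": series.sd1,
            "SD2": series.sd2,
            "CSI": series.csi,
            "CVI": series.cvi,
        }
    ).to_csv(path, index=False)


def write_metrics(series_list: list[MetricSeries], path) -> None:
    frames = []
    for ms in series_list:
        long = ms.values.reset_index().melt(
            id_vars="time", var_name="metric", value_name="value"
        )
        long.insert(1, "band", ms.band)
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_manifest(path, **params) -> None:
    """JSON run manifest: parameters, seed, and environment versions."""
    import bhnet

    manifest = {
        "package": "bhnet",
        "version": getattr(bhnet, "__version__", "unknown"),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "parameters": {
            k: (v if isinstance(v, (int, float, str, bool, list, dict)) else str(v))
            for k, v in params.items()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
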