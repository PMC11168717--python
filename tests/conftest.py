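import numpy as np
import pytest

from bhnet import BinaryGraph, IBISeries, SignalRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_binary_graph(rng, n, p=0.4, require_edge=True):
    """Random symmetric 0/1 graph with zero diagonal."""
    while True:
        a = (rng.random((n, n)) < p).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        if not require_edge or a.sum() > 0:
            return BinaryGraph(a)


def random_ibi(rng, n=200, base=0.85, sd=0.05):
    intervals = np.clip(base + sd * rng.standard_normal(n), 0.3, 2.0)
    return IBISeries(intervals=intervals, times=np.cumsum(intervals))


def sine_record(freq, rate=256.0, duration=20.0, n_channels=1, amp=1.0):
    t = np.arange(int(duration * rate)) / rate
    x = amp * np.sin(2 * np.pi * freq * t)
    samples = np.tile(x, (n_channels, 1))
    labels = tuple(f"ch{i}" for i in range(n_channels))
    return SignalRecord(samples=samples, rate=rate, labels=labels)
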