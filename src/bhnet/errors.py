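"""Exception hierarchy for the brain-heart coupling pipeline."""


class BHNetError(Exception):
    """Base class for all package errors."""


class InvalidBandError(BHNetError, ValueError):
    """A frequency band is empty or violates the Nyquist limit."""


class DataError(BHNetError, ValueError):
    """Input signal contains non-finite values or is otherwise unusable."""


class NoPeaksError(BHNetError, ValueError):
    """R-peak detection found no plausible heartbeats."""


class InsufficientDataError(BHNetError, ValueError):
    """Too few samples/beats/pairs for the requested computation."""


class DegenerateGeometryError(BHNetError, ValueError):
    """Poincare ellipse geometry is undefined (negative SD2 radicand)."""

    def __init__(self, radicand: float):
        self.radicand = float(radicand)
        super().__init__(
            f"SD2 radicand is negative ({radicand:.6g}); the Poincare "
            "ellipse is undefined for this interval series"
        )
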