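"""Exception hierarchy for cyclopred.

All package errors derive from :class:`CycloPredError` so callers can catch
one base class at CLI boundaries.
"""


class CycloPredError(Exception):
    """Base class for all cyclopred errors."""


class ParseError(CycloPredError):
    """A signal file could not be parsed (malformed row, missing header...)."""


class InvalidSignal(CycloPredError):
    """A breathing signal violates its invariants (non-increasing time, empty crop...)."""


class InvalidFilter(CycloPredError):
    """Filter specification is unusable at the signal's sampling rate."""


class NoPeaksDetected(CycloPredError):
    """No alternating maximum/minimum pair could be found."""


class InsufficientPeaks(CycloPredError):
    """Too few anchors to build envelopes."""


class DegenerateEnvelope(CycloPredError):
    """Envelope deflection is non-positive somewhere on the valid region."""


class InvalidComponents(CycloPredError):
    """Reassembly received invalid components (negative deflection)."""


class DegenerateWindow(CycloPredError):
    """A scaling window has zero dynamic range."""


class ShapeError(CycloPredError):
    """Array arguments have incompatible shapes or lengths."""


class EmptyEval(CycloPredError):
    """An evaluation was requested with no usable data points."""


class NoTrainingData(CycloPredError):
    """Training was requested with an empty sample set."""


class InvalidSplit(CycloPredError):
    """Train/validation split is impossible for the given datasets."""


class InvalidConfig(CycloPredError):
    """A configuration object violates its invariants."""


class RateMismatch(CycloPredError):
    """Signal sampling rate does not match the predictor's expected rate."""
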