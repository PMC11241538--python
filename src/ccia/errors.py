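"""Typed exceptions raised across the package."""


class CciaError(Exception):
    """Base class for all package errors."""


class ValidationError(CciaError, ValueError):
    """A domain object violates one of its invariants."""


class FormatError(CciaError, ValueError):
    """An on-disk artifact is unreadable or malformed."""


class RoiError(CciaError, ValueError):
    """An ROI is empty, out of bounds, or cannot be placed."""


class SignalError(CciaError, ValueError):
    """A trace is degenerate (flat ECG, absent contrast, too short)."""
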