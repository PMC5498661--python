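"""Exception hierarchy.

All errors raised by this package derive from :class:`HopfnetError`, so
callers can catch package failures without masking programming errors.
"""


class HopfnetError(Exception):
    """Base class for all hopfnet errors."""


class ParameterError(HopfnetError, ValueError):
    """A scalar parameter is outside its admissible range."""


class ShapeError(HopfnetError, ValueError):
    """Array dimensions are inconsistent with the operation."""


class DegenerateSignalError(HopfnetError, ValueError):
    """A time series is constant / zero-variance where variance is required."""


class DegenerateSpectrumError(HopfnetError, ValueError):
    """A spectrum is flat inside the analysis band; no peak can be defined."""


class TransformDomainError(HopfnetError, ValueError):
    """A value lies outside the domain of a transform (e.g. atanh(±1))."""


class DesignError(HopfnetError, ValueError):
    """The cohort design is invalid (unpaired subjects, empty train set...)."""


class IntegrationError(HopfnetError, RuntimeError):
    """Numerical integration produced a non-finite state."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
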