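"""Exception hierarchy for gpstest."""


class GpsTestError(Exception):
    """Base class for all gpstest errors."""


class InputValidationError(GpsTestError, ValueError):
    """Raised when an input vector or table violates a precondition."""


class DegenerateInputError(GpsTestError, ValueError):
    """Raised when every evaluation point of the statistic is degenerate
    (only possible when both p-value vectors are constant)."""


class SchemaError(GpsTestError, ValueError):
    """Raised when a summary-statistics file lacks a mapped column."""


class EmptyInputError(GpsTestError, ValueError):
    """Raised when ingestion or harmonisation leaves no usable rows."""


class InsufficientOverlapError(GpsTestError, ValueError):
    """Raised when two studies share fewer variants than the minimum."""


class GEVFitError(GpsTestError, RuntimeError):
    """Raised when the GEV maximum-likelihood fit fails to converge.

    Carries the best parameters found so far in ``params``
    (with ``converged == False``).
    """

    def __init__(self, message, params=None):
        super().__init__(message)
        self.params = params
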