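"""Exception hierarchy shared across the pipeline."""


class ChromatacError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ChromatacError, ValueError):
    """Invalid simulation or analysis parameters."""


class FormatError(ChromatacError, ValueError):
    """Malformed input file; message carries the offending line number."""


class InsufficientDataError(ChromatacError):
    """Too few observations to run an estimator.

    Parameters
    ----------
    message : str
    count : int, optional
        The number of observations that were available.
    """

    def __init__(self, message: str, count: int | None = None):
        super().__init__(message)
        self.count = count


class AnnotationConflictError(ChromatacError):
    """Overlapping annotation intervals where a partition is required."""


class BoundsError(ChromatacError, ValueError):
    """Interval extends beyond the end of its chromosome sequence."""


class UndefinedValueError(ChromatacError, ZeroDivisionError):
    """A ratio or content value whose denominator is zero/empty."""


class IncompleteDataError(ChromatacError):
    """A required record (e.g. a core histone) is absent."""
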