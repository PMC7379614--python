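"""Exception hierarchy.

Validation failures and QC aborts are distinct so that shell pipelines can
branch on exit status (see :mod:`rifdecay.cli`).
"""


class RifdecayError(Exception):
    """Base class for all package errors."""


class ValidationError(RifdecayError, ValueError):
    """Malformed or out-of-contract input. CLI exit status 2."""


class NoGrowthError(ValidationError):
    """Generation time requested on a non-growing segment (N <= N0)."""


class CurveRejectedError(ValidationError):
    """Standard curve is non-monotone or has a non-negative slope."""


class UndefinedCorrelationError(RifdecayError):
    """Correlation requested on a zero-variance vector."""


class QcAbortError(RifdecayError):
    """Too few samples survive QC to fit decay curves. CLI exit status 3."""

    def __init__(self, message: str, failing_samples: list[str] | None = None):
        super().__init__(message)
        self.failing_samples = failing_samples or []


class EmptySummaryError(ValidationError):
    """Summary statistics requested on an empty collection."""
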