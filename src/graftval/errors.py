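"""Exception types shared across the package."""


class GraftvalError(Exception):
    """Base class for all package-specific errors."""


class CohortFormatError(GraftvalError):
    """Raised when an input file cannot be parsed into a cohort.

    Carries a list of per-row messages (with line numbers) in ``rows``.
    """

    def __init__(self, message: str, rows: list[str] | None = None):
        super().__init__(message if not rows else message + "\n  " + "\n  ".join(rows))
        self.rows = rows or []


class LabValueError(GraftvalError):
    """A laboratory observation violates a domain invariant (e.g. value <= 0)."""


class InsufficientLabs(GraftvalError):
    """Too few laboratory observations to compute the requested feature/score."""
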