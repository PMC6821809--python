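"""Exception hierarchy for input validation.

All reader errors derive from :class:`DefaunationError` so callers can catch
one base class; :class:`RowError` carries the 1-based line number of the
offending row in the source file.
"""


class DefaunationError(Exception):
    """Base class for all package errors."""


class FormatError(DefaunationError):
    """A file is structurally malformed (missing columns, wrong delimiter)."""


class RowError(DefaunationError):
    """A single row failed validation.

    Parameters
    ----------
    message : str
        Description of the problem.
    line : int
        1-based line number in the source file (header is line 1).
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(DefaunationError):
    """Inputs are individually valid but mutually inconsistent."""


class ConvergenceWarning(UserWarning):
    """MCMC chains did not pass the Gelman-Rubin convergence check."""
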