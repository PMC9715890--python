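"""Exception hierarchy for the nodal staging score package."""


class NSSError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NSSError):
    """A required column, fit, or configuration entry is missing."""


class CohortValidationError(NSSError, ValueError):
    """Patient rows violate the cohort invariants.

    Carries ``rows``: a list of (row index, message) diagnostics so the
    offending records can be located in the source table.
    """

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class UndefinedRateError(NSSError, ValueError):
    """A rate was requested for an empty stratum."""


class FitError(NSSError, RuntimeError):
    """The maximum-likelihood fit cannot be run (too few usable patients)."""
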