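"""Exception hierarchy for healthineq.

All package-specific failures derive from :class:`HealthineqError` so callers
can catch one base class; subclasses distinguish validation failures from
numerical/degenerate-input failures.
"""


class HealthineqError(Exception):
    """Base class for all healthineq errors."""


class ParameterError(HealthineqError, ValueError):
    """Invalid configuration or generator parameter."""


class SchemaError(HealthineqError, ValueError):
    """A cohort table violates the column dictionary (missing column,
    out-of-range value, unseen categorical level...)."""


class DegenerateOutcomeError(HealthineqError, ValueError):
    """Outcome variable has too little variation to fit (e.g. a single
    observed self-rated-health level)."""


class NonConvergenceError(HealthineqError, RuntimeError):
    """Maximum-likelihood optimizer did not converge.

    Carries the optimizer diagnostics dict as ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateInputError(HealthineqError, ValueError):
    """Input vector is degenerate for the requested operation
    (e.g. constant latent health cannot be min-max rescaled)."""


class UndefinedIndexError(HealthineqError, ZeroDivisionError):
    """An index (CI, RD, coverage ratio) is undefined for this input,
    typically because a mean in the denominator is non-positive."""
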