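"""Exception hierarchy for the bcellfate pipeline."""


class BCellFateError(Exception):
    """Base class for all package-specific errors."""


class DomainError(BCellFateError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ConfigurationError(BCellFateError, ValueError):
    """A model specification or pipeline configuration is invalid."""


class InsufficientDataError(BCellFateError, ValueError):
    """Too few observations to perform the requested fit."""


class IntegrationError(BCellFateError, RuntimeError):
    """Numerical integration of the ODE system failed.

    Attributes
    ----------
    t_fail : float or None
        Time point (days post-immunization) at which the solver gave up.
    """

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class CohortParseError(BCellFateError, ValueError):
    """A cohort CSV violated the expected schema.

    Carries the offending row (1-based, excluding header) and column when known.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column
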