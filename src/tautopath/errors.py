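"""Exception hierarchy."""


class TautopathError(Exception):
    """Base class for all package-specific errors."""


class DomainError(TautopathError, ValueError):
    """A coordinate or parameter is outside its physical domain."""


class GeometryError(TautopathError, ValueError):
    """A geometric observable is undefined for the given configuration."""


class CalibrationError(TautopathError, RuntimeError):
    """The 1-D step potential cannot be calibrated to the requested barriers."""


class DegenerateWellError(CalibrationError):
    """Requested forward or reverse barrier is non-positive: no bound well."""


class ConvergenceError(TautopathError, RuntimeError):
    """An iterative optimisation failed to reach its tolerance.

    Carries the last iterate in ``last_state`` so callers can inspect or
    restart from it.
    """

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class BudgetError(ConvergenceError):
    """An evaluation budget was exhausted before convergence."""


class ClassificationError(TautopathError, ValueError):
    """An energy profile does not match an admissible stationary pattern."""


class NoOnsetError(TautopathError, ValueError):
    """No scanned separation supports a bound double-transfer minimum."""


class IntegrationError(TautopathError, RuntimeError):
    """Molecular-dynamics integration produced non-finite energies."""


class ParseError(TautopathError, ValueError):
    """A structure or configuration file is malformed."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class ConfigError(TautopathError, ValueError):
    """A run configuration failed validation."""
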