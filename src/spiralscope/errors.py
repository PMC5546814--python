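"""Exception hierarchy shared across the analysis stages.

Every stage raises a subclass of :class:`SpiralscopeError`, so pipeline
orchestration can isolate a failing stage without masking programming errors.
"""


class SpiralscopeError(Exception):
    """Base class for all errors raised by spiralscope."""


class ValidationError(SpiralscopeError):
    """Malformed input data (bad spike tables, inconsistent metadata)."""


class ParameterError(SpiralscopeError):
    """A parameter violates its documented precondition."""


class AlignmentError(SpiralscopeError):
    """Neuron sets or orderings do not match between two objects."""


class DegenerateInputError(SpiralscopeError):
    """Input is formally valid but carries no usable signal (e.g. all-zero rates)."""


class IntegrationError(SpiralscopeError):
    """Numerical integration produced a non-finite state."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class UndefinedComparisonError(SpiralscopeError):
    """A set comparison was requested on an empty point set."""


class InsufficientDataError(SpiralscopeError):
    """Too few observations to estimate the requested quantity."""


class SummaryUnavailableError(SpiralscopeError):
    """Too few valid local fits to summarise attractor dynamics."""


class UndefinedStatisticError(SpiralscopeError):
    """A statistic is undefined for the given inputs (e.g. zero total weight)."""


class ConvergenceError(SpiralscopeError):
    """An iterative fit failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
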