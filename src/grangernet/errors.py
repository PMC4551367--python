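"""Exception hierarchy.

Validation problems (bad files, bad parameters) and numerical failures
(singular designs, non-convergence) are kept apart so the CLI can map them
to distinct exit codes.
"""


class GrangerNetError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GrangerNetError):
    """An on-disk artifact violates the expected text format."""


class ParameterError(GrangerNetError):
    """A configuration value is out of its valid range."""


class InvalidOrderError(ParameterError):
    """The VAR model order is incompatible with the series length."""


class InsufficientDataError(ParameterError):
    """Too few time points for the requested statistic."""


class DegenerateSimulationError(GrangerNetError):
    """The simulator configuration left no usable genes."""


class NumericalError(GrangerNetError):
    """Base class for numerical failures."""


class SingularDesignError(NumericalError):
    """X'X is rank deficient; ordinary least squares is undefined."""


class ConvergenceError(NumericalError):
    """An iterative solver did not converge within its iteration budget."""


class DegenerateFitError(NumericalError):
    """A fit is too perfect (zero residual) for the requested test."""
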