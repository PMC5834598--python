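"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`LipoclassError`, so callers
(including the CLI) can distinguish configuration mistakes from bad input
data and from genuine numerical failures.
"""


class LipoclassError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LipoclassError, ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


class InputError(LipoclassError, ValueError):
    """Input data violates a precondition (shape, labels, emptiness...)."""


class StateError(LipoclassError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class NumericalError(LipoclassError, ArithmeticError):
    """A numerical step failed (singular covariance, non-finite values)."""


class ConvergenceError(LipoclassError, RuntimeError):
    """An iterative solver hit its iteration cap before converging."""


class UndefinedMetricError(LipoclassError, ZeroDivisionError):
    """A performance metric has a zero denominator and is undefined."""


class FormulaError(LipoclassError, ValueError):
    """A molecular formula string could not be parsed."""
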