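"""Exception hierarchy shared across the package."""


class MLMRError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MLMRError, ValueError):
    """A configuration parameter is outside its valid range."""


class InvalidInputError(MLMRError, ValueError):
    """Input data violates a precondition (shape, NaN, encoding...)."""


class InfeasibleGraphError(MLMRError, ValueError):
    """The requested graph (e.g. a b-regular subgraph) cannot exist."""


class NoLabeledInstancesError(MLMRError, ValueError):
    """Semi-supervised fitting requires at least one labeled instance."""


class NumericalError(MLMRError, ArithmeticError):
    """A linear system was singular or too ill-conditioned to trust."""


class UndefinedMetricError(MLMRError, ValueError):
    """A metric is undefined for the given input (e.g. no relevant labels)."""
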