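"""Exception and warning types shared across metnet modules."""


class MetnetError(Exception):
    """Base class for all metnet errors."""


class InvalidModelError(MetnetError):
    """The SBML document does not describe a usable metabolic model."""


class GPRParseError(MetnetError, ValueError):
    """A gene-association rule string is not a valid boolean expression."""


class ExpressionParseError(MetnetError, ValueError):
    """An expression table cell could not be interpreted as a number."""


class EmptyGraphError(MetnetError):
    """Graph construction produced no edges (or no nodes after cleanup)."""


class ConvergenceError(MetnetError):
    """An iterative numerical routine failed to converge."""


class ModelValidationWarning(UserWarning):
    """Non-fatal irregularity found while validating a parsed model."""


class GraphConstructionWarning(UserWarning):
    """Non-fatal irregularity found while building or weighting a graph."""
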