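"""Exception types raised across the package."""


class GPKinError(Exception):
    """Base class for all package errors."""


class SchemaError(GPKinError):
    """A required column is missing from an input table."""


class ValidationError(GPKinError):
    """Input values violate a domain invariant (negative c0/t, bad replicate, ...)."""


class EmptyInputError(GPKinError):
    """A table or dataset contains no data rows."""


class EvaluationError(GPKinError):
    """A model is non-finite where a finite value is required."""


class ParseError(GPKinError):
    """Malformed expression string; carries the offending position."""

    def __init__(self, message, position=None):
        super().__init__(message if position is None
                         else f"{message} (at position {position})")
        self.position = position


class PruneError(GPKinError):
    """Requested subtree removal would leave an arity-invalid tree."""


class ArityError(GPKinError):
    """Parameter-vector length does not match the tree's parameter slots."""


class FitError(GPKinError):
    """No optimization start produced a finite objective."""


class InsufficientDataError(GPKinError):
    """Jackknife requires more observations than free parameters."""


class DegenerateRunError(GPKinError):
    """Every candidate model in a GP run was non-finite on the data."""


class DecompositionError(GPKinError):
    """Expression cannot be split into additive components."""


class UndefinedRSquaredError(GPKinError):
    """Total sum of squares is zero; R^2 undefined."""


class NoModelError(GPKinError):
    """Model selection invoked on an empty candidate set."""
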