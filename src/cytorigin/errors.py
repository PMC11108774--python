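"""Exception taxonomy shared across the package."""


class CytoriginError(Exception):
    """Base class for all package errors."""


class DimensionError(CytoriginError, ValueError):
    """An image or array is too small / mis-shaped for the requested operation."""


class UnsupportedInputError(CytoriginError, TypeError):
    """Operation received an input kind it cannot process (e.g. feature-only bag)."""


class ExcludedSubgroupError(CytoriginError, KeyError):
    """Fine subgroup is recognized but deliberately outside the 5-category taxonomy."""


class UnknownLabelError(CytoriginError, KeyError):
    """Fine subgroup is not in the taxonomy at all."""


class SchemaError(CytoriginError, ValueError):
    """A manifest/table is missing required columns or has invalid rows."""


class IntegrityError(CytoriginError, ValueError):
    """Duplicate case ids or other cross-row consistency violations."""


class EmptyBagError(CytoriginError, ValueError):
    """A bag with zero instances reached an operation requiring at least one."""


class IncompleteCovariatesError(CytoriginError, ValueError):
    """Clinical covariates are missing a required field."""


class ParameterError(CytoriginError, ValueError):
    """A numeric hyperparameter is outside its valid range."""


class DataError(CytoriginError, ValueError):
    """A dataset-level precondition failed (empty split, no events, ...)."""


class ConfigurationError(CytoriginError, ValueError):
    """Mutually inconsistent configuration values."""


class ScheduleExhaustedError(CytoriginError, ValueError):
    """Learning-rate schedule queried past its final epoch."""


class ConvergenceError(CytoriginError, RuntimeError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []
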