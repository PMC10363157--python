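"""Exception hierarchy for the UAOD kinetics pipeline."""


class UAODError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(UAODError, ValueError):
    """A scalar or array argument violates a precondition (e.g. A0 <= 0)."""


class InconsistentRecordError(UAODError, ValueError):
    """A mass record is physically impossible (e.g. solids exceed total mass)."""


class ConfigurationError(UAODError, ValueError):
    """A model/parameter-map/pipeline configuration is incomplete or malformed."""


class InsufficientDataError(UAODError, ValueError):
    """Too few usable data points for the requested estimate."""


class SchemaError(UAODError, ValueError):
    """An input table does not conform to the trajectory CSV schema."""


class SelectionError(UAODError, ValueError):
    """Model selection was requested but no converged fit is available."""
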