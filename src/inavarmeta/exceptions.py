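"""Exception and warning hierarchy shared across the package."""


class InavarmetaError(Exception):
    """Base class for all package errors."""


class FormatError(InavarmetaError):
    """A file does not conform to the expected CSV layout (e.g. bad header)."""


class DatasetError(InavarmetaError):
    """A dataset is unusable as a whole (e.g. zero valid rows)."""


class SchemaError(InavarmetaError, KeyError):
    """A field name is not part of the experiment-record schema."""


class RecordError(InavarmetaError):
    """One or more records violate the record-level invariants."""


class ConsistencyError(InavarmetaError):
    """Redundant fields (SD and SEM) disagree beyond tolerance."""


class FitError(InavarmetaError):
    """Nonlinear curve fitting failed or its preconditions were not met."""


class ArtifactError(InavarmetaError):
    """The self-consistent voltage-error solve did not converge."""


class ConfigError(InavarmetaError):
    """A simulation configuration is invalid."""


class IllConditionedWarning(UserWarning):
    """Data geometry makes the requested fit poorly constrained."""


class BoundaryWarning(UserWarning):
    """An optimum landed on the edge of the search grid."""


class BranchWarning(UserWarning):
    """A fitted slope factor has the wrong sign for the requested branch."""


class TruncationWarning(UserWarning):
    """A moment estimate was negative and has been truncated at zero."""
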