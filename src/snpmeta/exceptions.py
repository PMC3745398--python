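"""Exception hierarchy shared across the package."""


class SnpMetaError(Exception):
    """Base class for all package errors."""


class FormatError(SnpMetaError):
    """Input file does not conform to the documented TSV dialect."""


class TableValidationError(SnpMetaError):
    """A study row violates an invariant (addressed by study_id where possible)."""


class DomainError(SnpMetaError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class CapabilityError(SnpMetaError):
    """The requested analysis is not computable from the data a record carries."""


class NonEstimableError(SnpMetaError):
    """An effect or pooled estimate is undefined even after continuity correction."""


class InsufficientStudiesError(SnpMetaError):
    """Fewer studies than the statistic's minimum k."""
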