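"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`MirefscanError`, so callers (and the CLI) can distinguish data
problems from genuine bugs.
"""


class MirefscanError(Exception):
    """Base class for all package errors."""


class InvalidNameError(MirefscanError):
    """An entity name is empty or cannot be normalized."""


class SchemaError(MirefscanError):
    """An input table is missing required columns or is not square."""


class DataError(MirefscanError):
    """Input values violate a contract (asymmetry, negative similarity...)."""


class AlignmentError(MirefscanError):
    """Two labeled matrices do not share the same label ordering."""


class NotFoundError(MirefscanError):
    """A requested entity is absent from the store."""


class UnsupportedDiseaseError(MirefscanError):
    """The disease has no known interactions, so no seed labels exist."""


class CoverageError(MirefscanError):
    """A similarity matrix does not cover all required entities."""


class ConfigError(MirefscanError):
    """A configuration object violates its invariants."""


class UndefinedCorrelationError(MirefscanError):
    """Correlation is undefined (constant vector, too few points)."""


class UndefinedResultError(MirefscanError):
    """A summary was requested for an empty collection."""


class NumericalError(MirefscanError):
    """A linear system could not be solved even with ridge regularization."""
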