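"""Exception hierarchy shared across the pipeline stages."""


class GanglioseqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GanglioseqError, ValueError):
    """A configuration object or threshold set violates its invariants."""


class ValidationError(GanglioseqError, ValueError):
    """An input table or vector violates a precondition."""


class AnnotationError(GanglioseqError, KeyError):
    """A gene referenced by the count matrix is missing from the annotation."""


class DegenerateSampleError(GanglioseqError, ValueError):
    """A sample has zero total counts and cannot be depth-normalized."""


class EstimationError(GanglioseqError, RuntimeError):
    """A statistical estimate is undefined for the given data."""


class EmptyMappingError(GanglioseqError, ValueError):
    """Ortholog mapping between two datasets produced no shared genes."""
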