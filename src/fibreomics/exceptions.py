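"""Exception hierarchy shared across the pipeline stages."""


class FibreomicsError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FibreomicsError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class ShapeError(FibreomicsError, ValueError):
    """Input arrays have inconsistent lengths or shapes."""


class DegenerateTraceError(FibreomicsError, ValueError):
    """A fluorescence trace cannot be normalised (non-positive t=0 signal)."""


class InsufficientDataError(FibreomicsError, ValueError):
    """Too few frames, fibres, groups or participants for the operation."""


class UntypeableFibreError(FibreomicsError, ValueError):
    """No MYH isoform was quantified in the fibre, so no subtype can be called."""


class UndefinedCorrelationError(FibreomicsError, ValueError):
    """Correlation undefined because one of the vectors has zero variance."""


class FormatError(FibreomicsError, ValueError):
    """A protein-group matrix or annotation file violates the expected layout."""
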