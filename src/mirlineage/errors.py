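"""Exception hierarchy for mirlineage.

All package errors derive from :class:`MirlineageError` so callers can catch
one base class; subclasses tag the pipeline stage that raised them.
"""


class MirlineageError(Exception):
    """Base class for all mirlineage errors."""


class ConfigurationError(MirlineageError):
    """A simulation or pipeline configuration violates one of its constraints."""


class ParseError(MirlineageError):
    """A tab-delimited input file is malformed (duplicate ids, ragged rows,
    non-numeric cells).  The message names the offending id and line."""


class MappingError(MirlineageError):
    """A probe in an expression matrix has no entry in the probe map."""


class NormalizationError(MirlineageError):
    """Global median normalization is impossible (non-positive sample median)."""


class DegenerateArrayError(MirlineageError):
    """An array (sample column) has zero variance and cannot be z-scored."""


class GroupingError(MirlineageError):
    """Sample class definitions overlap, are unknown, or are too small."""


class InsufficientOverlapError(MirlineageError):
    """Too few samples are shared between the miRNA and mRNA matrices."""


class FeatureLookupError(MirlineageError):
    """A requested feature id does not exist in the probe map."""


class ValidationError(MirlineageError):
    """A numeric input violates its contract (e.g. p-values outside (0, 1])."""
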