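"""Exception hierarchy for kaksel.

Every error raised by the package derives from :class:`KakselError` so callers
can catch domain failures without masking programming errors.
"""


class KakselError(Exception):
    """Base class for all kaksel errors."""


class AlignmentShapeError(KakselError):
    """Sequences of unequal length (ragged alignment)."""


class FrameError(KakselError):
    """Alignment length not divisible by three."""


class IdentifierError(KakselError):
    """Duplicate or unknown taxon / species identifiers."""


class StopCodonError(KakselError):
    """In-frame stop codon found during validation."""


class SchemaError(KakselError):
    """Malformed metadata or configuration table."""


class NewickParseError(KakselError):
    """Unparseable Newick string."""


class ParameterError(KakselError):
    """Model parameter outside its admissible range."""


class DataError(KakselError):
    """Degenerate data (e.g. alignment with no usable codons)."""


class SizeGuardError(KakselError):
    """Brute-force oracle invoked on an instance beyond its size guard."""


class CladeError(KakselError):
    """A declared clade is not monophyletic in the tree."""


class NestingError(KakselError):
    """Likelihood ratio test requested for non-nested model specs."""


class OptimizationError(KakselError):
    """Alternative model fit worse than null beyond tolerance; refit needed."""


class EmptyResultError(KakselError):
    """Filtering removed every element."""


class NumericalError(KakselError):
    """Non-finite likelihood or probability encountered."""
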