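"""Exception hierarchy for the pipeline.

Every error raised on user input derives from :class:`DomainRatesError` so the
CLI can catch one type and exit with a stage-tagged message.
"""


class DomainRatesError(Exception):
    """Base class for all pipeline errors."""


class ParseError(DomainRatesError):
    """Malformed input file; message names the file and line where known."""


class AlignmentShapeError(DomainRatesError):
    """Rows of an aligned FASTA differ in length."""


class ValidationError(DomainRatesError):
    """An annotation table or config violates its invariants."""


# subclass of ValidationError: callers catching validation failures must also
# see coordinate problems
class CoordinateError(ValidationError):
    """A region interval or residue position falls outside the reference."""


class ModelError(DomainRatesError):
    """Substitution-model inputs are inconsistent (e.g. zero frequency)."""


class UndefinedDistanceError(DomainRatesError):
    """A sequence pair shares no comparable columns."""


class TreeError(DomainRatesError):
    """Tree-level contract violation (missing taxa, unrooted input, ...)."""
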