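"""Exception hierarchy.

All package-specific failures derive from :class:`MemevoError` so callers can
distinguish input problems from computation bugs with a single except clause.
"""


class MemevoError(Exception):
    """Base class for all errors raised by memevo."""


class ParseError(MemevoError):
    """A file or string could not be parsed (names the record/offset)."""


class AlignmentShapeError(MemevoError):
    """Gapped sequences in an alignment do not share a common length."""


class ValidationError(MemevoError):
    """Input content violates a documented invariant (bad clade, dup ids...)."""


class TruncationError(MemevoError):
    """A flank region would extend past the ends of the protein."""


class InputError(MemevoError):
    """An operation was called with unusable inputs (empty sample, no columns)."""


class GenerationError(MemevoError):
    """A synthetic-data request is internally inconsistent or infeasible."""
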