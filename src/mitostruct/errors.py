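"""Exception hierarchy.

All package errors derive from :class:`MitostructError` so callers can catch
one type; the subclasses distinguish malformed files from semantically
invalid (but parseable) input and from inconsistent simulation plans.
"""


class MitostructError(Exception):
    """Base class for all mitostruct errors."""


class FormatError(MitostructError, ValueError):
    """A file could not be parsed (missing columns, bad coordinates...)."""


class ValidationError(MitostructError, ValueError):
    """Parsed input violates a domain invariant (e.g. start > end on a
    linear record, sequence/length mismatch)."""


class AlignmentError(FormatError):
    """A FASTA alignment has ragged rows or no usable sites."""


class SpecError(MitostructError, ValueError):
    """A synthetic-data plan is internally inconsistent."""
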