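"""Exception hierarchy for input validation and degenerate-data conditions."""


class ValidationError(ValueError):
    """Input violates a documented precondition or type invariant."""


class FormatError(ValidationError):
    """A file does not conform to its declared dialect."""


class IdentifierCollisionError(ValidationError):
    """Duplicate gene, sample or set identifiers where uniqueness is required."""


class EmptySetError(ValidationError):
    """A gene set has no members in the data being analysed."""


class NoSignalError(ValidationError):
    """No sample carries the alteration the operation is asked to summarise."""


class NoOverlapError(ValidationError):
    """Homolog collapse or gene-space intersection left nothing to analyse."""


class UndefinedCorrelationError(ValidationError):
    """Pearson correlation requested against a zero-variance profile."""
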