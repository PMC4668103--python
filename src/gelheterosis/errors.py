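"""Exception hierarchy for table validation and degenerate statistics."""


class GelHeterosisError(Exception):
    """Base class for all package errors."""


class TableParseError(GelHeterosisError):
    """A tabular input file could not be parsed (malformed row, bad header)."""


class ValidationError(GelHeterosisError, ValueError):
    """A table or parameter violates a declared invariant."""


class DegenerateGelError(GelHeterosisError, ValueError):
    """A gel (genotype x stage x replicate) has zero total intensity."""


class DegenerateVarianceError(GelHeterosisError, ValueError):
    """A statistical test is undefined because within-group variance is zero."""


class DomainError(GelHeterosisError, ValueError):
    """An argument is outside the mathematical domain of an operation."""
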