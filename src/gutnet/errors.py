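"""Exception hierarchy shared across the package."""


class GutnetError(Exception):
    """Base class for all errors raised by gutnet."""


class IdentifierError(GutnetError):
    """Duplicate or otherwise invalid taxon/sample identifiers."""


class TableFormatError(GutnetError):
    """A cell or header in an input table cannot be parsed."""


class ReconciliationError(GutnetError):
    """Count matrix and sample metadata do not describe the same samples."""


class EmptyResultError(GutnetError):
    """An operation removed every taxon or sample."""


class UsageError(GutnetError):
    """An argument is outside the operation's domain."""


class UndefinedIndexError(GutnetError):
    """A niche or diversity index is undefined for the given input."""


class ConvergenceError(GutnetError):
    """An iterative solver failed to reach the requested tolerance."""


class DesignError(GutnetError):
    """Group structure is insufficient for the requested test."""
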