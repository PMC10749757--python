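"""Exception hierarchy.

Every user-facing failure mode raises a subclass of :class:`CrossGexError`
so callers (and the CLI) can distinguish bad input from genuine bugs.
"""


class CrossGexError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CrossGexError):
    """A file does not conform to its expected dialect (missing column,
    wrong field count, unparsable value)."""


class ValidationError(CrossGexError):
    """Data parsed fine but violates an invariant (negative counts,
    duplicate keys, unknown species)."""


class SelectionError(CrossGexError):
    """A gene/tissue/species selection resolved to nothing, or named
    entries absent from the table."""


class FitError(CrossGexError):
    """A model fit (dispersion trend) could not be performed on the
    supplied data."""
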