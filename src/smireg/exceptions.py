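"""Exception hierarchy shared across the package."""


class SmiregError(Exception):
    """Base class for all package errors."""


class FormatError(SmiregError):
    """A file does not conform to its declared format (missing column, bad header...)."""


class ValidationError(SmiregError):
    """Well-formed input that violates a semantic invariant (duplicates, bad alphabet...)."""
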