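"""Shared exception hierarchy.

Every error a caller may want to branch on derives from :class:`SemcdsError`.
The CLI maps subclasses to distinct exit codes (config 2, validation 3,
not-found/not-classifiable 4, anything else 5).
"""


class SemcdsError(Exception):
    """Base class for all package errors."""


class ConfigError(SemcdsError):
    """Bad paths, options out of range, unreadable configuration."""


class ValidationError(SemcdsError):
    """Structurally well-formed input that violates a semantic contract."""


class ParseError(ValidationError):
    """Malformed input row/cell; message names the offending location."""


class VocabularyError(ValidationError):
    """A value outside a closed controlled vocabulary."""


class NotClassifiableError(SemcdsError):
    """No staging rule covers the record (clinically invalid combination)."""


class NotFoundError(SemcdsError):
    """Lookup of an id that is absent from the graph/corpus."""
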