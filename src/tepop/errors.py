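"""Exception hierarchy shared across the package.

Three failure classes are distinguished so that callers (and the CLI exit
codes) can react differently to malformed files, semantically invalid data,
and statistics that are undefined for the given input.
"""


class TepopError(Exception):
    """Base class for all package errors."""


class FormatError(TepopError):
    """A file could not be parsed (bad cell, bad header, bad dialect)."""


class ValidationError(TepopError):
    """Parsed data violates a domain invariant."""


class UndefinedStatisticError(TepopError):
    """A requested statistic is undefined for the given input."""
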