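"""Exception hierarchy.

Parsers and validators raise :class:`ValidationError` (CLI exit code 1);
anything else unexpected surfaces as a runtime failure (CLI exit code 2).
"""


class RibotideError(Exception):
    """Base class for all package errors."""


class ValidationError(RibotideError, ValueError):
    """Malformed or inconsistent input data or configuration."""


class ParseError(ValidationError):
    """A file could not be parsed; message carries the location."""
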