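"""Exception hierarchy shared across the package."""


class ArrayscanError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ArrayscanError):
    """Malformed or inconsistent input data (files or records)."""


class ValidationError(ArrayscanError):
    """Parameter or precondition violation in an operation call."""
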