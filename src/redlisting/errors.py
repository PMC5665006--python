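"""Exception hierarchy.

``UsageError`` maps to CLI exit code 1 (bad invocation), ``DataError`` to
exit code 2 (the inputs themselves are unusable).
"""


class RedlistingError(Exception):
    """Base class for all package errors."""


class UsageError(RedlistingError):
    """The caller asked for something invalid (bad parameter, bad flag)."""


class DataError(RedlistingError):
    """The input data cannot support the requested computation."""
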