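"""Exception hierarchy shared across the package."""


class EmplexError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EmplexError, ValueError):
    """Raised when a configuration object is internally inconsistent."""


class FormatError(EmplexError, ValueError):
    """Raised when an on-disk file does not parse in the declared dialect."""


class ValidationError(EmplexError, ValueError):
    """Raised when in-memory data violates a container invariant."""


class EmptyResultError(EmplexError, ValueError):
    """Raised when a filtering step removes every cell (or gene)."""
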