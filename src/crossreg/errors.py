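"""Exception types shared across the package."""


class CrossRegError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CrossRegError, ValueError):
    """A configuration value is missing, inconsistent, or out of range."""


class ValidationError(CrossRegError, ValueError):
    """An input record or matrix violates its documented invariants."""
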