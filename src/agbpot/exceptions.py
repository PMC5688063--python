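"""Exception hierarchy shared across the package."""


class AgbpotError(Exception):
    """Base class for all package errors."""


class DomainError(AgbpotError, ValueError):
    """An argument is outside its mathematical/physical domain."""


class ConfigurationError(AgbpotError, ValueError):
    """A configuration value is invalid or inconsistent."""


class FormatError(AgbpotError, ValueError):
    """An on-disk file does not match the expected layout."""


class SchemaError(AgbpotError, ValueError):
    """Feature schema of inputs does not match a fitted model."""
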