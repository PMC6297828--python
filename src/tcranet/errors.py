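"""Exception types shared across the package."""


class TcranetError(Exception):
    """Base class for package errors."""


class ValidationError(TcranetError, ValueError):
    """Input data violates a documented invariant (exit code 1 in the CLI)."""


class ConfigurationError(TcranetError, ValueError):
    """A configuration value or column mapping is unusable (exit code 1)."""
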