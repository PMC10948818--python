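"""Exception hierarchy.

CLI exit-code convention: 0 success, 1 data error, 2 configuration error.
"""


class UrbifluxError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(UrbifluxError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigError(UrbifluxError):
    """A configuration value violates a type invariant."""


class SchemaError(UrbifluxError):
    """A file is missing required columns/variables or unit metadata."""


class DataError(UrbifluxError):
    """Data content is unusable (non-monotone time axis, NaN forcing...)."""


class NumericalError(UrbifluxError):
    """A numerical routine failed to reach its tolerance."""
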