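"""Exception types shared across the package."""


class ArscapeError(Exception):
    """Base class for package errors."""


class ConfigError(ArscapeError, ValueError):
    """A run or column configuration is invalid (e.g. a mapped column is missing)."""


class DataError(ArscapeError, ValueError):
    """Input data violate an invariant (e.g. duplicate timestamps)."""
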