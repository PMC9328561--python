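"""Exception hierarchy for the accessibility pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and its
subclasses) -> 3, anything else -> 4.
"""


class FcaError(Exception):
    """Base class for all package errors."""


class ConfigError(FcaError):
    """Invalid configuration: bad parameter values, unknown keys, unknown presets."""


class DataError(FcaError):
    """Invalid input data: schema violations, dangling references, bad geometries."""


class SchemaError(DataError):
    """A required column or field is missing or has the wrong shape."""


class ValidationError(DataError):
    """A row or feature fails a value-level constraint (negative count, no services...)."""
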