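"""Exception types shared across pipeline stages."""


class CsfMirError(Exception):
    """Base class for all package errors."""


class SchemaError(CsfMirError):
    """Input file does not conform to the expected schema."""


class DuplicateRecordError(SchemaError):
    """Two rows describe the same (sample, probe) reaction."""


class InvalidInputError(CsfMirError):
    """A value is outside its legal domain."""


class InsufficientDataError(CsfMirError):
    """Not enough usable observations to run an operation."""


class ConfigError(CsfMirError):
    """A configuration is internally inconsistent."""
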