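"""Package-specific exception types."""


class PvsignalError(Exception):
    """Base class for all pvsignal errors."""


class SchemaError(PvsignalError):
    """A required table or column is missing or unreadable."""


class ValidationError(PvsignalError):
    """User-supplied configuration or arguments are invalid."""


class EncodingError(PvsignalError):
    """Input bytes could not be decoded with the requested encoding."""


class FitError(PvsignalError):
    """A model fit failed on degenerate input."""
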