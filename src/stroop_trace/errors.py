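"""Exception types raised by the pipeline."""


class StroopTraceError(Exception):
    """Base class for all package errors."""


class ConfigError(StroopTraceError, ValueError):
    """A configuration value is invalid; the message names the field."""


class FormatError(StroopTraceError, ValueError):
    """An input file does not match the documented CSV format."""


class DataError(StroopTraceError, ValueError):
    """Input data violate a contract (e.g. non-monotone sample times)."""


class AlignmentError(StroopTraceError, ValueError):
    """A trajectory cannot be anchored (degenerate start/end geometry)."""


class FitError(StroopTraceError, RuntimeError):
    """Model estimation failed beyond recovery."""
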