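"""Exception hierarchy shared across the pipeline."""


class HeartriskError(Exception):
    """Base class for all package errors."""


class FormatError(HeartriskError):
    """A record file could not be parsed (wrong field count, bad number)."""


class ValidationError(HeartriskError):
    """A value violates the record schema or an operation's domain."""


class ConfigError(HeartriskError):
    """A configuration object is internally inconsistent."""


class FittingError(HeartriskError):
    """An encoder could not be fitted from the given records."""


class DimensionError(HeartriskError):
    """Array shapes are inconsistent with the configured network."""


class NumericError(HeartriskError):
    """A non-finite value appeared where a finite one is required."""


class TrainingError(HeartriskError):
    """Training diverged or was asked to do something impossible."""
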