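"""Exception types shared across the pipeline."""


class SomnotraitError(Exception):
    """Base class for package errors."""


class ConfigurationError(SomnotraitError):
    """Invalid configuration value or inconsistent configuration."""


class DataError(SomnotraitError):
    """Malformed or inconsistent input data."""


class InvalidRecordError(DataError):
    """A night record violates its invariants (e.g. zero time in bed)."""


class InsufficientNightsError(DataError):
    """Fewer nights than required for a within-subject statistic."""


class ConstantInputError(DataError):
    """A statistic is undefined because an input variable is constant."""


class ExtractionError(SomnotraitError):
    """Factor extraction failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
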