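"""Exception hierarchy shared across the package."""


class TractAdjustError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(TractAdjustError):
    """An unknown or malformed candidate-model specification."""


class InsufficientDataError(TractAdjustError):
    """Too few observations (or too little length variation) to fit a model."""


class SchemaError(TractAdjustError):
    """Input table does not conform to the expected long-format schema."""


class NoValidModelError(TractAdjustError):
    """No candidate model produced a finite information criterion."""


class DegenerateWeightsError(TractAdjustError):
    """The breakpoint models jointly carry zero Akaike weight, so no
    inflection-point reference value is defined for the subject."""


class UndefinedCorrelationError(TractAdjustError):
    """Rank correlation undefined (e.g. one sample entirely tied)."""


class EmptyRunError(TractAdjustError):
    """The pipeline was invoked with no usable subjects."""
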