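"""Exception hierarchy for cochleashape.

All domain errors derive from :class:`CochleaError` so callers (and the CLI)
can distinguish contract violations from programming errors.
"""


class CochleaError(ValueError):
    """Base class for all domain errors raised by this package."""


class FormatError(CochleaError):
    """A table or file does not conform to the expected format."""


class ValidationError(CochleaError):
    """A record or population violates a data-model invariant."""


class UnderdeterminedError(CochleaError):
    """Too few distinct sample positions for the requested fit."""


class DomainError(CochleaError):
    """An input value is outside the mathematical domain of an operation."""


class ImplausiblePredictionWarning(UserWarning):
    """A predicted cochlea is geometrically implausible (non-positive radius
    or angular length below one turn).  The prediction is still returned."""
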