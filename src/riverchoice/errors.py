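"""Exception hierarchy shared across the pipeline."""


class RiverChoiceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RiverChoiceError):
    """Invalid run or landscape configuration."""


class DomainError(RiverChoiceError):
    """A point or value lies outside the domain an operation requires."""


class EdgeError(RiverChoiceError):
    """A transect or window ran off the end of the landscape."""


class FitError(RiverChoiceError):
    """Model fitting failed in a way that cannot be reported as a fit."""


class ChoiceDataError(RiverChoiceError):
    """Malformed choice-set data (parsing or structural violations)."""
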