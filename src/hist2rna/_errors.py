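"""Exception hierarchy shared across the package."""


class Hist2RNAError(Exception):
    """Base class for all package errors."""


class InvalidInputError(Hist2RNAError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(Hist2RNAError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ConfigurationError(Hist2RNAError, ValueError):
    """A configuration value is unknown or inconsistent."""


class EstimationError(Hist2RNAError, RuntimeError):
    """A statistical estimate could not be computed from the given data."""


class StateError(Hist2RNAError, RuntimeError):
    """An operation was applied to an object in the wrong state."""


class AlignmentError(Hist2RNAError, ValueError):
    """Identifiers of two containers do not match up."""
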