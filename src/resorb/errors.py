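"""Exception hierarchy shared by all pipeline stages."""


class ResorbError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(ResorbError):
    """An input table is missing a required column."""


class ValidationError(ResorbError):
    """A value violates a domain invariant (wrong enum, non-positive concentration ...)."""


class PairingError(ResorbError):
    """A site lacks one of the two sampling periods needed for pairing."""


class DegenerateFitError(ResorbError):
    """A regression cannot be estimated (constant predictor, zero slope SE)."""


class InsufficientDataError(ResorbError):
    """Fewer valid observations remain than the analysis requires."""


class ConfigurationError(ResorbError):
    """A required option or file is missing or inconsistent."""
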