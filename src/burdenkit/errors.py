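"""Exception hierarchy shared across burdenkit modules."""


class BurdenkitError(Exception):
    """Base class for all burdenkit errors."""


class ValidationError(BurdenkitError):
    """Input violates a documented precondition or invariant."""


class InsufficientGrowthError(BurdenkitError):
    """Too few usable points above the OD floor to estimate a growth rate."""


class UndefinedRatioError(BurdenkitError):
    """A ratio or correlation is mathematically undefined for this input."""


class ConfigError(BurdenkitError):
    """A run configuration is inconsistent or references missing inputs."""
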