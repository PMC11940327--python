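"""Exception hierarchy for the chemoreflex package."""


class ChemoreflexError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ChemoreflexError, ValueError):
    """Invalid configuration (bad parameter values, unknown keys)."""


class ValidationError(ChemoreflexError, ValueError):
    """Input data violate a documented precondition."""


class InsufficientDataError(ValidationError):
    """Not enough data to perform the requested computation."""


class AnalysisError(ChemoreflexError, RuntimeError):
    """Analysis cannot proceed (e.g. irregular rhythm, degenerate fit)."""
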