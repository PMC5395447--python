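"""Exception hierarchy shared across the package."""


class ParapatryError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ParapatryError, ValueError):
    """Input data violate a documented precondition or invariant."""


class ConfigurationError(ParapatryError, ValueError):
    """A configuration object or file is invalid."""


class FitError(ParapatryError, RuntimeError):
    """Model fitting cannot proceed (degenerate data, failed sampler)."""


class ComputationError(ParapatryError, ValueError):
    """A statistic is undefined for the given input."""


class StratificationError(ParapatryError, ValueError):
    """Stratified folds cannot be constructed for the requested k."""


class DiagnosticError(ParapatryError, ValueError):
    """A convergence diagnostic cannot be computed."""
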