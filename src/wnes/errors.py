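"""Exception hierarchy shared across the package."""


class WnesError(Exception):
    """Base class for all package-specific errors."""


class NetworkStructureError(WnesError, ValueError):
    """The directed network violates a structural requirement (cycle, self-loop, ...)."""


class ConfigurationError(WnesError, ValueError):
    """Invalid user configuration (weight family, tuning constant, flags)."""


class DataInputError(WnesError, ValueError):
    """Malformed or insufficient input data (missing columns, too few samples, ...)."""


class EstimationError(WnesError, RuntimeError):
    """Edge-coefficient estimation failed (rank-deficient parent design)."""


class DegenerateDataError(WnesError, ValueError):
    """A statistic denominator is zero while its numerator is not."""


class InfeasibleScenarioError(WnesError, ValueError):
    """Variance rectification would require a non-positive error variance."""
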