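"""Exception and warning types shared across the package."""


class RafResistError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RafResistError, ValueError):
    """A model parameter violates its domain (e.g. non-positive concentration)."""


class NumericalError(RafResistError, RuntimeError):
    """A solver failed to converge; the message names the offending residual."""


class RegimeError(RafResistError, ValueError):
    """A closed-form approximation was evaluated outside its regime of validity."""


class ConfigurationError(RafResistError, ValueError):
    """A scenario/config file failed schema validation."""


class NetworkOverflowError(RafResistError, RuntimeError):
    """Rule expansion exceeded the configured species cap."""


class RegimeWarning(UserWarning):
    """Emitted when an approximation is used near the edge of its validity."""


class ConvergenceWarning(UserWarning):
    """Emitted when a steady-state result did not meet the stationarity threshold."""
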