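"""Exception hierarchy shared across the package."""


class TgfsmadError(Exception):
    """Base class for all package-specific errors."""


class DomainError(TgfsmadError, ValueError):
    """A parameter or state value lies outside its mathematical domain."""


class ConvergenceError(TgfsmadError, RuntimeError):
    """An iterative solver failed to converge within its budget."""


class SimulationError(TgfsmadError, RuntimeError):
    """The ODE integrator failed.

    Attributes
    ----------
    t_fail : float or None
        Time (min) at which integration failed, if known.
    """

    def __init__(self, message, t_fail=None):
        super().__init__(message)
        self.t_fail = t_fail


class UndefinedObservableError(TgfsmadError, ValueError):
    """A derived readout is undefined (e.g. division by a zero pool)."""


class UndefinedElasticityError(TgfsmadError, ValueError):
    """Log-elasticity requested at a point where the response is zero."""


class NonIdentifiableEC50Error(TgfsmadError, ValueError):
    """Dose-response data too flat to constrain an EC50."""


class EC50OutOfRangeError(TgfsmadError, ValueError):
    """Fitted curve never crosses the half-response level.

    Attributes
    ----------
    bracket : tuple
        (min response, max response) of the fitted curve over the data span.
    """

    def __init__(self, message, bracket=None):
        super().__init__(message)
        self.bracket = bracket


class EstimationFailedError(TgfsmadError, RuntimeError):
    """All optimization starts failed."""


class SchemaError(TgfsmadError, ValueError):
    """A table does not match the declared schema."""


class ConfigError(TgfsmadError, ValueError):
    """Configuration file invalid; message names the offending key."""
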