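"""Exception hierarchy for atriawave."""


class AtriawaveError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(AtriawaveError):
    """Cell state contains non-finite or otherwise unusable values."""


class ParameterError(AtriawaveError):
    """A model or generator parameter violates its constraints."""


class ConfigurationError(AtriawaveError):
    """A scenario, study config, or file reference is inconsistent."""


class ShapeError(AtriawaveError):
    """Array dimensions do not match the cell geometry or trace layout."""


class SimulationFailedError(AtriawaveError):
    """The integrator diverged or produced NaN.

    Carries ``t_failure`` (ms), the time at which integration became
    invalid, so callers can map the run to the "other" wave category.
    """

    def __init__(self, message: str, t_failure: float | None = None):
        super().__init__(message)
        self.t_failure = t_failure


class NoActionPotentialError(AtriawaveError):
    """No upstroke was found in a voltage trace."""


class InsufficientDataError(AtriawaveError):
    """Too few beats or samples for the requested statistic."""
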