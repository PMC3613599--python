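"""Exception types shared across the package."""


class AmygsimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AmygsimError, ValueError):
    """A parameter value violates its documented constraints."""


class StructuralError(AmygsimError, ValueError):
    """Mismatched array lengths or otherwise ill-formed state."""


class NumericalError(AmygsimError, RuntimeError):
    """Divergence, NaN/Inf, or an out-of-bound weight during integration."""

    def __init__(self, message: str, trial_index: int | None = None):
        super().__init__(message)
        self.trial_index = trial_index


class ConfigurationError(AmygsimError, ValueError):
    """Unknown preset name, unresolvable stimulus label, or bad config file."""
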