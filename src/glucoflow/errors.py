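"""Exception hierarchy for glucoflow."""


class GlucoflowError(Exception):
    """Base class for all glucoflow errors."""


class ConfigurationError(GlucoflowError):
    """A parameter, segment or config entry is structurally invalid."""


class InvalidStateError(GlucoflowError):
    """A physical state variable (volume, concentration) is out of range."""


class IntegrationError(GlucoflowError):
    """The ODE solver failed or produced non-finite state."""


class FitError(GlucoflowError):
    """A nonlinear or polynomial fit could not be performed."""
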