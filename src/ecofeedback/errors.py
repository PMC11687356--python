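"""Exception hierarchy."""


class EcoFeedbackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EcoFeedbackError):
    """Structural problem: dimension mismatch, bad grid spec, invalid config."""


class ValidationError(EcoFeedbackError):
    """Invalid data: negative concentrations/abundances, malformed tables."""


class ModelEvaluationError(EcoFeedbackError):
    """A model function returned a non-finite or mis-shaped value."""


class IntegrationError(EcoFeedbackError):
    """The ODE/PDE solver failed; carries the last valid state when known."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state
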