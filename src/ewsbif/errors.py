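"""Exception hierarchy shared by all ewsbif modules."""


class EwsbifError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EwsbifError):
    """Unknown model family, missing parameter, or malformed configuration."""


class DomainError(EwsbifError):
    """Inputs outside the mathematical domain of an operation."""


class IntegrationBlowupError(EwsbifError):
    """SDE integration produced a non-finite state.

    Carries the step index (and trajectory index when available) so the
    offending run can be located.
    """

    def __init__(self, message, step=None, trajectory=None):
        super().__init__(message)
        self.step = step
        self.trajectory = trajectory


class EstimatorError(EwsbifError):
    """An estimator is undefined for the given samples (e.g. constant series)."""


class LoadError(EwsbifError):
    """A distribution table failed validation on load."""
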