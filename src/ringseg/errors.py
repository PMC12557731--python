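"""Exception hierarchy for ringseg."""


class RingsegError(Exception):
    """Base class for all ringseg errors."""


class InvalidParameterError(RingsegError, ValueError):
    """A physical or schedule parameter violates its constraints."""


class ConfigurationInvariantError(RingsegError, ValueError):
    """A bead/bond configuration violates a structural invariant."""


class ConfigFileError(RingsegError, ValueError):
    """A run-configuration file is missing, unparsable, or has bad keys."""


class GenerationError(RingsegError, RuntimeError):
    """An initial-state generator failed after bounded retries."""


class IntegrationError(RingsegError, RuntimeError):
    """A single Brownian step produced a non-finite displacement."""


class InstabilityError(RingsegError, RuntimeError):
    """The integrator lost containment or ring topology mid-run."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class DegenerateConfigurationError(RingsegError, ValueError):
    """The discriminant problem is singular beyond repair."""
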