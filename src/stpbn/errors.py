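"""Exception types raised across the package."""


class StpbnError(Exception):
    """Base class for all package-specific errors."""


class ExpressionError(StpbnError, ValueError):
    """Malformed Boolean expression text or an undeclared symbol.

    ``position`` is the 0-based character offset into the source text at
    which the problem was detected, or ``None`` when not applicable.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class NetworkError(StpbnError, ValueError):
    """Invalid Boolean network definition (unbound inputs, bad names...)."""


class SynthesisError(StpbnError, ValueError):
    """Feedback-control synthesis cannot succeed for the requested inputs."""


class TrajectoryError(StpbnError, ValueError):
    """A trajectory is too short for the requested decomposition."""
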