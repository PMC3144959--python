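"""Exception hierarchy for the cardiostain pipeline."""


class CardiostainError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CardiostainError, ValueError):
    """A parameter violates its documented domain."""


class FormatError(CardiostainError, ValueError):
    """An input array/file does not have the expected layout."""


class DegenerateInputError(CardiostainError, ValueError):
    """Input is too degenerate for the requested operation (e.g. fewer
    distinct colors than clusters)."""


class InvalidPartitionError(CardiostainError, ValueError):
    """A left/right partition polyline is not usable (not y-monotone,
    repeated points, ...)."""


class GeometryError(CardiostainError, RuntimeError):
    """Phantom geometry could not be realized with the given parameters."""


class ConfigError(CardiostainError, ValueError):
    """A run configuration is invalid."""


class StageError(CardiostainError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
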