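"""Exception hierarchy shared across the package."""


class PostureKitError(Exception):
    """Base class for all package-specific errors."""


class MalformedDetectionError(PostureKitError):
    """A fiducial detection does not carry exactly four corners."""


class UndefinedAngleError(PostureKitError):
    """An angle was requested between coincident points."""


class InvalidSampleError(PostureKitError):
    """An acceleration sample is unusable (e.g. zero-norm vector)."""


class ConfigurationError(PostureKitError):
    """A configuration value is invalid (unknown dictionary, bad IDs...)."""


class SensorFormatError(PostureKitError):
    """A sensor CSV is missing required columns."""


class SensorOrderingError(PostureKitError):
    """Sensor timestamps are not strictly increasing."""


class LayoutError(PostureKitError):
    """Requested synthetic geometry does not fit the canvas."""


class EmptySessionError(PostureKitError):
    """A summary or report was requested for an empty session."""


class UndefinedCorrelationError(PostureKitError):
    """Correlation undefined: series too short or zero variance."""
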