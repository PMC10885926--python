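"""Exception hierarchy shared across the package."""


class VidSpo2Error(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(VidSpo2Error, ValueError):
    """A parameter is outside its admissible range."""


class InsufficientLengthError(VidSpo2Error, ValueError):
    """A signal or clip is too short for the requested operation."""


class DegenerateSignalError(VidSpo2Error, ValueError):
    """A signal is constant, all-zero, or otherwise uninformative."""


class ShapeError(VidSpo2Error, ValueError):
    """Array shapes or lengths are inconsistent."""


class AlignmentError(VidSpo2Error, ValueError):
    """Reference signals do not cover the video they should label."""


class DetectionFailureError(VidSpo2Error, RuntimeError):
    """No region of interest could be found."""


class DataError(VidSpo2Error, ValueError):
    """A dataset, manifest, or sample is missing required pieces."""


class StateError(VidSpo2Error, RuntimeError):
    """A required checkpoint or training state is absent."""


class ConfigError(VidSpo2Error, ValueError):
    """An experiment configuration is invalid."""


class LeakageError(VidSpo2Error, RuntimeError):
    """Test-subject data leaked into a training fold."""
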