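"""Exception hierarchy shared across the package."""


class TeledermoError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TeledermoError, ValueError):
    """A caller-supplied parameter violates an operation's preconditions."""


class FormatError(TeledermoError, ValueError):
    """Input raster or signal is not in the expected format."""


class SegmentationError(TeledermoError, RuntimeError):
    """No lesion could be detected in the image."""


class InsufficientPairsError(TeledermoError, RuntimeError):
    """No valid pixel pair exists at the requested offset inside the mask."""


class ScalingError(TeledermoError, ValueError):
    """A feature value fell outside the [0, 1] range expected of scaled DPs."""


class CapacityError(TeledermoError, ValueError):
    """The carrier is too short for the requested payload layout."""


class SideInfoMismatchError(TeledermoError, ValueError):
    """Extraction side information is inconsistent with the received signal."""
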