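"""Exception hierarchy for the segmentation pipeline."""


class DirVesselError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DirVesselError):
    """Input raster does not meet the format contract (e.g. single-channel)."""


class GeometryError(DirVesselError):
    """Shape mismatch between rasters that must share one geometry."""


class ConfigurationError(DirVesselError):
    """A configuration value violates its invariant."""


class EstimationError(DirVesselError):
    """Automatic FOV-mask estimation failed."""


class DegenerateInputError(DirVesselError):
    """Input is constant or otherwise carries no usable signal."""


class NumericalStabilityError(DirVesselError):
    """Non-finite values appeared during an iterative computation."""
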