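"""Exception hierarchy for the grainmorph pipeline."""


class GrainMorphError(Exception):
    """Base class for all grainmorph errors."""


class ImageFormatError(GrainMorphError):
    """Raised for unreadable files or images that are not 24-bit colour rasters."""


class CalibrationError(GrainMorphError):
    """Raised for non-positive or otherwise invalid scan resolutions."""


class PlacementError(GrainMorphError):
    """Raised when a synthetic kernel cannot be placed (overlap / out of bounds).

    Carries the index of the offending kernel spec in ``spec_index``.
    """

    def __init__(self, message: str, spec_index: int | None = None):
        super().__init__(message)
        self.spec_index = spec_index


class MeasurementError(GrainMorphError):
    """Raised for invalid caliper measurements (non-positive dimensions, wrong counts)."""


class RegressionError(GrainMorphError):
    """Raised when a linear fit is not defined (constant x, too few points, orphan ids)."""


class ConfigError(GrainMorphError):
    """Raised for unknown or out-of-range pipeline configuration values."""
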