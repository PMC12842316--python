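"""Exception hierarchy shared across the package."""


class MangovolError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MangovolError, ValueError):
    """An argument is outside its documented domain."""


class GeometryError(MangovolError, ValueError):
    """A mask or scene violates a geometric precondition
    (empty mask, dimension mismatch, out-of-bounds or overlapping elements)."""


class CalibrationError(GeometryError):
    """The fiducial marker cannot yield a valid pixel-to-metric scale
    (e.g. zero marker area). Such images are excluded from analysis."""


class DegenerateCaseError(MangovolError, ValueError):
    """A statistic is undefined on the given data
    (constant truth vector, zero-variance paired differences, ...)."""


class MaskFormatError(MangovolError, ValueError):
    """An image file decoded but does not contain a usable mask."""
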