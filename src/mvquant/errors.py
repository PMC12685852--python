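"""Exception hierarchy for mvquant.

All package errors derive from :class:`MVQuantError` so callers can catch
pipeline failures (e.g. a frame whose annulus ring cannot be closed) without
swallowing programming errors.
"""


class MVQuantError(Exception):
    """Base class for all mvquant errors."""


class PhantomSizeError(MVQuantError):
    """The requested grid cannot contain the tilted phantom with margin."""


class SplineFitError(MVQuantError):
    """Control-point configuration unsuitable for B-spline fitting."""


class CurveBoundsError(MVQuantError):
    """A sampled curve leaves the world bounds of the template volume."""


class EmptyMaskError(MVQuantError):
    """An operation that requires a nonempty binary mask received none."""


class MissingAnnulusError(MVQuantError):
    """Label volume carries no annulus (label 3) voxels."""


class DegeneratePathError(MVQuantError):
    """Too few points to order into a centerline path."""


class DegeneratePlaneError(MVQuantError):
    """Points are (near-)collinear; no unique best-fit plane exists."""


class EmptyProjectionError(MVQuantError):
    """Volume contains no labelled voxels to project."""


class OpenRingError(MVQuantError):
    """Projected annulus ring does not enclose a region even after closing.

    Attributes
    ----------
    gap_mm : float
        Estimated size of the largest gap in the ring (NaN when the ring is
        a single open arc whose gap cannot be located).
    """

    def __init__(self, message: str, gap_mm: float = float("nan")):
        super().__init__(message)
        self.gap_mm = gap_mm


class EmptyCurveError(MVQuantError):
    """No frame of a sequence produced a valid measurement."""


class UndefinedCorrelationError(MVQuantError):
    """Pearson correlation undefined (zero variance in a series)."""


class VolumeFormatError(MVQuantError):
    """File cannot be interpreted as an integer label volume."""


class MetadataError(MVQuantError):
    """Spacing/affine metadata missing or invalid."""
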