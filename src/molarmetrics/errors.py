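"""Exception hierarchy for the measurement pipeline.

Every failure mode that corresponds to an excludable radiograph (closed
apices, degenerate masks) raises a dedicated subclass of
:class:`MolarMetricsError` so that batch runs can record the reason per
tooth and keep going.
"""


class MolarMetricsError(Exception):
    """Base class for all package-specific errors."""


class EmptyMaskError(MolarMetricsError):
    """A mask with zero true pixels was passed where pixels are required."""


class MaskOverlapError(MolarMetricsError):
    """Apical and coronal masks overlap; the two-part segmentation is invalid."""


class DegenerateGeometryError(MolarMetricsError):
    """Geometry collapsed (coincident barycenters, empty wall, missing side...)."""


class ClosedApexError(MolarMetricsError):
    """No open root canal could be found; mirrors the study's exclusion of
    radiographs without two visible apices."""


class AnnotationSchemaError(MolarMetricsError):
    """A labelme-dialect document does not contain exactly one apical and one
    coronal polygon shape."""


class ImageFormatError(MolarMetricsError):
    """The raster is not a single-channel grayscale image."""


class ShapeMismatchError(MolarMetricsError):
    """Two arrays/series that must share a shape or length do not."""


class ConstantSeriesError(MolarMetricsError):
    """A statistic is undefined because a series has zero variance."""


class LabelError(MolarMetricsError):
    """Decision labels are not binary / not from the expected label set."""


class InvalidMeasurementError(MolarMetricsError):
    """A measurement violates its invariants (non-positive height, negative ratio)."""


class PhantomGeometryError(MolarMetricsError):
    """The requested phantom parameters cannot be realized as a valid tooth."""
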