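"""Calibrated geometric features from binary masks.

Converts per-view instance masks into the nine physical descriptors used
for volume regression:

=========  =============================================  =====
feature    definition                                     unit
=========  =============================================  =====
A_s        side-view fruit area                           cm^2
A_b        bottom-view fruit area                         cm^2
A_s15      A_s ** 1.5 (power-law, scales like a volume)   cm^3
A_b15      A_b ** 1.5                                     cm^3
h          fruit height, side view (long rect side)       cm
w          fruit width, bottom view (long rect side)      cm
d1         depth estimate, side view (short rect side)    cm
d2         depth estimate, bottom view (short rect side)  cm
V_e        ellipsoid volume (4/3)*pi*(h/2)(w/2)(d1+d2)/4  cm^3
=========  =============================================  =====

Per-image calibration uses the fiducial marker of known physical area
(default 900 mm^2, a 30 mm square): ``R_area = area_mm2 / marker_px``
(mm^2/px) and ``R_length = sqrt(R_area)`` (mm/px, isotropic scaling).
Calibrating every image individually removes the dependence on the
camera-to-object distance.

Dimension features come from the minimum-area rotated rectangle of the
largest connected foreground component.  The rectangle is fitted to the
convex hull of the boundary pixels expanded by the four half-pixel corner
offsets (i.e. the hull of the pixel *squares*, not the pixel centers):
measuring center-to-center spans would systematically undersize every
dimension by one pixel.  Side lengths are kept sub-pixel (never rounded)
and converted px -> mm -> cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint

from .exceptions import CalibrationError, GeometryError, ParameterError
from . import masks as mio

__all__ = [
    "CalibrationScale",
    "ViewFeatures",
    "FeatureVector",
    "calibration_from_marker",
    "physical_area",
    "min_area_rect_of_points",
    "min_area_rect_dims",
    "side_view_features",
    "bottom_view_features",
    "ellipsoid_volume",
    "extract_features",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["A_s", "A_b", "A_s15", "A_b15", "h", "w", "d1", "d2", "V_e"]


@dataclass(frozen=True)
class CalibrationScale:
    """Per-image pixel-to-metric conversion ratios (isotropic)."""

    r_area: float  # mm^2 per px

    def __post_init__(self):
        if self.r_area <= 0:
            raise CalibrationError("r_area must be positive")

    @property
    def r_length(self) -> float:
        """mm per px; sqrt of the area ratio under isotropic scaling."""
        return math.sqrt(self.r_area)


@dataclass(frozen=True)
class ViewFeatures:
    view: str
    area: float  # cm^2
    dim_long: float  # cm
    dim_short: float  # cm

    def __post_init__(self):
        if self.area <= 0 or self.dim_short <= 0 or self.dim_long < self.dim_short:
            raise GeometryError("view features must satisfy area>0, long>=short>0")


@dataclass(frozen=True)
class FeatureVector:
    """The nine descriptors of one fruit, two views fused.

    The power-law features and the ellipsoid volume are derived properties,
    recomputed on access so they can never drift out of sync with the
    stored areas and dimensions.
    """

    a_s: float
    a_b: float
    h: float
    w: float
    d1: float
    d2: float

    @property
    def a_s15(self) -> float:
        return self.a_s**1.5

    @property
    def a_b15(self) -> float:
        return self.a_b**1.5

    @property
    def v_e(self) -> float:
        return ellipsoid_volume(self.h, self.w, self.d1, self.d2)

    def as_row(self) -> dict[str, float]:
        return {
            "A_s": self.a_s,
            "A_b": self.a_b,
            "A_s15": self.a_s15,
            "A_b15": self.a_b15,
            "h": self.h,
            "w": self.w,
            "d1": self.d1,
            "d2": self.d2,
            "V_e": self.v_e,
        }


def calibration_from_marker(marker_mask: np.ndarray, marker_area_mm2: float = 900.0) -> CalibrationScale:
    """Scale from the rendered/segmented marker: R_area = known_mm2 / pixel_count."""
    if marker_area_mm2 <= 0:
        raise ParameterError("marker_area_mm2 must be positive")
    count = mio.foreground_count(marker_mask)
    if count == 0:
        raise CalibrationError("zero marker area: image excluded from calibration")
    return CalibrationScale(r_area=marker_area_mm2 / count)


def physical_area(pixel_count: int, scale: CalibrationScale) -> float:
    """Pixel count -> cm^2 (r_area is mm^2/px; 100 mm^2 per cm^2)."""
    if pixel_count < 0:
        raise ParameterError("pixel_count must be >= 0")
    return pixel_count * scale.r_area / 100.0


def min_area_rect_of_points(points: np.ndarray) -> tuple[float, float]:
    """Side lengths (long, short) of the minimum-area rotated rectangle.

    ``points`` is an (n, 2) array of planar coordinates.  Degenerate inputs
    (a single point, collinear points) yield rectangles with zero side(s).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise GeometryError("need an (n, 2) array with n >= 1")
    if len(pts) >= 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear: fall through with all points
    rect = MultiPoint(pts).minimum_rotated_rectangle
    if rect.geom_type == "Point":
        return 0.0, 0.0
    if rect.geom_type == "LineString":
        (x0, y0), (x1, y1) = rect.coords[0], rect.coords[-1]
        return math.hypot(x1 - x0, y1 - y0), 0.0
    xy = np.asarray(rect.exterior.coords)
    s1 = float(np.hypot(*(xy[1] - xy[0])))
    s2 = float(np.hypot(*(xy[2] - xy[1])))
    return max(s1, s2), min(s1, s2)


_EIGHT = np.ones((3, 3), bool)
_CORNERS = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask != 0, structure=_EIGHT)
    if n == 0:
        raise GeometryError("empty mask")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def mask_boundary_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corner points of the boundary pixels of the largest component.

    Returns (m, 2) coordinates in (x=col, y=row) axes.  Each boundary pixel
    center (c+0.5, r+0.5) contributes its four square corners, so the hull
    of the returned set equals the hull of the union of pixel squares.
    """
    comp = _largest_component(mask)
    interior = ndimage.binary_erosion(comp, structure=_EIGHT, border_value=0)
    rr, cc = np.nonzero(comp & ~interior)
    centers = np.column_stack([cc + 0.5, rr + 0.5])
    if len(centers) >= 3:
        try:
            centers = centers[ConvexHull(centers).vertices]
        except QhullError:
            pass
    return (centers[:, None, :] + _CORNERS[None, :, :]).reshape(-1, 2)


def min_area_rect_dims(mask: np.ndarray, scale: CalibrationScale) -> tuple[float, float]:
    """(long, short) sides in cm of the min-area rectangle of a mask.

    Operates on the outer contour of the largest connected component
    (holes are ignored); a single-pixel mask yields a 1 px x 1 px square,
    the documented degenerate case.
    """
    long_px, short_px = min_area_rect_of_points(mask_boundary_corner_points(mask))
    factor = scale.r_length / 10.0  # px -> mm -> cm
    return long_px * factor, short_px * factor


def _view_features(mask: np.ndarray, scale: CalibrationScale, view: str) -> ViewFeatures:
    count = mio.foreground_count(mask)
    if count == 0:
        raise GeometryError(f"empty fruit mask in {view} view")
    area = physical_area(count, scale)
    dim_long, dim_short = min_area_rect_dims(mask, scale)
    return ViewFeatures(view=view, area=area, dim_long=dim_long, dim_short=dim_short)


def side_view_features(fruit_mask: np.ndarray, scale: CalibrationScale) -> ViewFeatures:
    """Side view: h := longer rectangle side, d1 := shorter.

    The larger/smaller assignment mirrors the bottom-view rule; the mask is
    expected to be calyx-excluded (upstream contract).
    """
    return _view_features(fruit_mask, scale, "side")


def bottom_view_features(fruit_mask: np.ndarray, scale: CalibrationScale) -> ViewFeatures:
    """Bottom view: w := longer rectangle side, d2 := shorter."""
    return _view_features(fruit_mask, scale, "bottom")


def ellipsoid_volume(h: float, w: float, d1: float, d2: float) -> float:
    """V_e = (4/3) * pi * (h/2) * (w/2) * ((d1 + d2)/4), all lengths in cm.

    The three orthogonal radii are half the side-view height, half the
    bottom-view width, and the mean of the two half-depth estimates.
    """
    if min(h, w, d1, d2) <= 0:
        raise ParameterError("all dimensions must be positive")
    return (4.0 / 3.0) * math.pi * (h / 2.0) * (w / 2.0) * ((d1 + d2) / 4.0)


def _as_triple(view) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if hasattr(view, "fruit_mask"):  # RenderedScene duck type
        return view.fruit_mask, view.calyx_mask, view.marker_mask
    fruit, calyx, marker = view
    return fruit, calyx, marker


def extract_features(
    side,
    bottom,
    marker_area_mm2: float = 900.0,
    exclude_calyx: bool = True,
) -> FeatureVector:
    """Assemble the nine-feature vector from the two orthogonal views.

    ``side`` and ``bottom`` are either RenderedScene objects or
    ``(fruit_mask, calyx_mask, marker_mask)`` triples.  Each view is
    calibrated from its own marker.  With ``exclude_calyx`` (the default,
    and the intended pipeline), calyx pixels are subtracted from the fruit
    mask before any measurement; ``exclude_calyx=False`` unions them back
    in, reproducing the degraded no-segmentation condition.
    """
    view_feats = {}
    for name, view in (("side", side), ("bottom", bottom)):
        fruit, calyx, marker = _as_triple(view)
        try:
            scale = calibration_from_marker(marker, marker_area_mm2)
        except CalibrationError as exc:
            raise CalibrationError(f"{name} view: {exc}") from exc
        if exclude_calyx:
            work = mio.subtract_mask(fruit, calyx)
        else:
            work = mio.union_mask(fruit, calyx)
        try:
            fn = side_view_features if name == "side" else bottom_view_features
            view_feats[name] = fn(work, scale)
        except GeometryError as exc:
            raise GeometryError(f"{name} view fruit mask: {exc}") from exc
    s, b = view_feats["side"], view_feats["bottom"]
    return FeatureVector(
        a_s=s.area, a_b=b.area, h=s.dim_long, d1=s.dim_short, w=b.dim_long, d2=b.dim_short
    )
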