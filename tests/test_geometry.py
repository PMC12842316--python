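"""Calibration, min-area-rectangle dimensions and feature extraction."""

import math

import numpy as np
import pytest
from scipy import ndimage

from mangovol import masks as mio
from mangovol.exceptions import CalibrationError, GeometryError, ParameterError
from mangovol.geometry import (
    CalibrationScale,
    FeatureVector,
    calibration_from_marker,
    ellipsoid_volume,
    extract_features,
    min_area_rect_dims,
    physical_area,
    side_view_features,
    bottom_view_features,
)
from mangovol.synth import FruitSpec, default_scene, render_scene

UNIT = CalibrationScale(r_area=1.0)  # 1 mm^2 / px


def filled(h, w, r0, c0, hh, ww):
    m = np.zeros((h, w), np.uint8)
    m[r0 : r0 + hh, c0 : c0 + ww] = 255
    return m


# --- calibration -----------------------------------------------------------


def test_calibration_arithmetic():
    marker = filled(60, 60, 5, 5, 30, 30)  # 900 px
    scale = calibration_from_marker(marker)
    assert scale.r_area == pytest.approx(1.0)
    assert scale.r_length == pytest.approx(1.0)

    big = filled(120, 120, 0, 0, 100, 100)  # 10000 px
    scale = calibration_from_marker(big)
    assert scale.r_area == pytest.approx(0.09)
    assert scale.r_length == pytest.approx(0.3)


def test_empty_marker_is_calibration_error():
    with pytest.raises(CalibrationError):
        calibration_from_marker(np.zeros((10, 10), np.uint8))


def test_physical_area_conversion():
    assert physical_area(1000, UNIT) == pytest.approx(10.0)
    assert physical_area(0, UNIT) == 0.0
    with pytest.raises(ParameterError):
        physical_area(-1, UNIT)


def test_circle_area_through_full_calibration_path():
    """A rendered 2.5 cm sphere, calibrated via its own marker, must give
    the analytic disk area to 1%."""
    f = FruitSpec(id="c", semi_axis_h=2.5, semi_axis_w=2.5, semi_axis_d=2.5)
    rendered = render_scene(f, default_scene(f, "side", 0.5))
    scale = calibration_from_marker(rendered.marker_mask)
    area = physical_area(mio.foreground_count(rendered.fruit_mask), scale)
    assert area == pytest.approx(math.pi * 2.5**2, rel=0.01)


# --- min-area rectangle ----------------------------------------------------


def test_axis_aligned_rectangle_dims_exact():
    mask = filled(60, 80, 10, 20, 20, 40)
    long_cm, short_cm = min_area_rect_dims(mask, UNIT)
    assert long_cm == pytest.approx(4.0, abs=0.1)  # +-1 px tolerance
    assert short_cm == pytest.approx(2.0, abs=0.1)


def test_rotated_rectangle_dims_within_3pct():
    # 120x60 px rectangle rotated 45 degrees, rasterized via the polygon path
    c, half_l, half_s = 150.0, 60.0, 30.0
    u = math.sqrt(0.5)
    corners = []
    for sl, ss in ((1, 1), (1, -1), (-1, -1), (-1, 1)):
        corners.append(
            (c + sl * half_l * u - ss * half_s * u, c + sl * half_l * u + ss * half_s * u)
        )
    mask = mio.polygon_to_mask(corners, 300, 300)
    long_cm, short_cm = min_area_rect_dims(mask, UNIT)
    assert long_cm == pytest.approx(12.0, rel=0.03)
    assert short_cm == pytest.approx(6.0, rel=0.03)


def test_filled_circle_bounding_square():
    yy, xx = np.mgrid[:80, :80]
    mask = np.where((yy - 40.0) ** 2 + (xx - 40.0) ** 2 < 30.0**2, 255, 0).astype(np.uint8)
    long_cm, short_cm = min_area_rect_dims(mask, UNIT)
    assert long_cm == pytest.approx(6.0, rel=0.02)
    assert short_cm == pytest.approx(6.0, rel=0.02)


def test_single_pixel_mask_degenerate():
    mask = np.zeros((10, 10), np.uint8)
    mask[4, 7] = 255
    long_cm, short_cm = min_area_rect_dims(mask, UNIT)
    assert long_cm == pytest.approx(0.1)  # 1 px -> 1 mm -> 0.1 cm
    assert short_cm == pytest.approx(0.1)


def test_empty_mask_raises():
    with pytest.raises(GeometryError):
        min_area_rect_dims(np.zeros((5, 5), np.uint8), UNIT)


def test_rect_uses_largest_component():
    mask = filled(60, 80, 10, 10, 20, 40)
    mask[50:53, 60:63] = 255  # small distractor blob
    long_cm, short_cm = min_area_rect_dims(mask, UNIT)
    assert long_cm == pytest.approx(4.0, abs=0.1)
    assert short_cm == pytest.approx(2.0, abs=0.1)


# --- view features ---------------------------------------------------------


def prolate():
    return FruitSpec(id="p", semi_axis_h=3.0, semi_axis_w=2.0, semi_axis_d=2.0)


def test_side_view_features_of_prolate_fruit():
    rendered = render_scene(prolate(), default_scene(prolate(), "side", 0.5))
    scale = calibration_from_marker(rendered.marker_mask)
    vf = side_view_features(rendered.fruit_mask, scale)
    assert vf.dim_long == pytest.approx(6.0, rel=0.02)  # h
    assert vf.dim_short == pytest.approx(4.0, rel=0.02)  # d1
    assert vf.area == pytest.approx(math.pi * 3.0 * 2.0, rel=0.02)


def test_bottom_view_features_of_oblate_fruit():
    f = FruitSpec(id="o", semi_axis_h=2.2, semi_axis_w=2.5, semi_axis_d=2.0)
    rendered = render_scene(f, default_scene(f, "bottom", 0.5))
    scale = calibration_from_marker(rendered.marker_mask)
    vf = bottom_view_features(rendered.fruit_mask, scale)
    assert vf.dim_long == pytest.approx(5.0, rel=0.02)  # w
    assert vf.dim_short == pytest.approx(4.0, rel=0.02)  # d2
    assert vf.dim_long >= vf.dim_short


def test_empty_fruit_mask_raises():
    with pytest.raises(GeometryError):
        side_view_features(np.zeros((10, 10), np.uint8), UNIT)


# --- ellipsoid volume ------------------------------------------------------


def test_ellipsoid_volume_closed_forms():
    assert ellipsoid_volume(2, 2, 2, 2) == pytest.approx(4.0 / 3.0 * math.pi, rel=1e-12)
    assert ellipsoid_volume(4, 2, 2, 2) == pytest.approx(8.3775804, rel=1e-6)
    with pytest.raises(ParameterError):
        ellipsoid_volume(1, 1, 0, 1)
    with pytest.raises(ParameterError):
        ellipsoid_volume(-1, 1, 1, 1)


# --- feature vector assembly -----------------------------------------------


def render_pair(fruit, mm_per_px=0.5):
    return (
        render_scene(fruit, default_scene(fruit, "side", mm_per_px)),
        render_scene(fruit, default_scene(fruit, "bottom", mm_per_px)),
    )


def test_spherical_fruit_volume_recovered_within_2pct():
    f = FruitSpec(id="s", semi_axis_h=2.327, semi_axis_w=2.327, semi_axis_d=2.327)
    side, bottom = render_pair(f)
    fv = extract_features(side, bottom)
    assert fv.v_e == pytest.approx(f.volume, rel=0.02)
    assert fv.h == pytest.approx(2 * 2.327, rel=0.02)


def test_power_law_features_are_recomputed_identities():
    fv = FeatureVector(a_s=10.0, a_b=7.0, h=5.0, w=4.8, d1=4.5, d2=4.4)
    assert fv.a_s15 == pytest.approx(31.6227766, rel=1e-8)  # 10^1.5
    assert fv.a_b15 == 7.0**1.5
    assert fv.v_e == ellipsoid_volume(5.0, 4.8, 4.5, 4.4)


def test_calyx_inclusion_strictly_inflates_side_area():
    f = FruitSpec(
        id="c", semi_axis_h=2.3, semi_axis_w=2.3, semi_axis_d=2.2,
        calyx_lobes=5, calyx_lobe_radius=0.5, calyx_protrusion=0.3,
    )
    side, bottom = render_pair(f)
    excl = extract_features(side, bottom, exclude_calyx=True)
    incl = extract_features(side, bottom, exclude_calyx=False)
    assert incl.a_s > excl.a_s
    assert incl.a_b == excl.a_b  # no calyx in the bottom view


def test_superset_mask_never_shrinks_features():
    f = prolate()
    side, bottom = render_pair(f)
    scale = calibration_from_marker(side.marker_mask)
    base = side_view_features(side.fruit_mask, scale)
    grown_mask = mio.binarize(
        ndimage.binary_dilation(side.fruit_mask != 0, iterations=2)
    )
    grown = side_view_features(grown_mask, scale)
    assert grown.area >= base.area
    assert grown.dim_long >= base.dim_long
    assert grown.dim_short >= base.dim_short


def test_extract_features_names_failing_view():
    f = prolate()
    side, bottom = render_pair(f)
    bad_marker = np.zeros_like(bottom.marker_mask)
    with pytest.raises(CalibrationError, match="bottom"):
        extract_features(side, (bottom.fruit_mask, bottom.calyx_mask, bad_marker))
    empty_fruit = np.zeros_like(side.fruit_mask)
    with pytest.raises(GeometryError, match="side"):
        extract_features((empty_fruit, side.calyx_mask, side.marker_mask), bottom)
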