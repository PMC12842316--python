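"""Mask I/O, rasterization, selection and segmentation metrics."""

import math

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from shapely.geometry import Polygon

from mangovol import masks as mio
from mangovol.exceptions import GeometryError, ParameterError


def square_mask(h, w, r0, c0, size):
    m = np.zeros((h, w), np.uint8)
    m[r0 : r0 + size, c0 : c0 + size] = 255
    return m


small_masks = arrays(
    np.uint8, (8, 8), elements=st.sampled_from([0, 255])
)


# --- I/O -------------------------------------------------------------------


def test_png_round_trip_preserves_pixels(tmp_path):
    rng = np.random.default_rng(0)
    mask = mio.binarize(rng.integers(0, 2, (31, 17)))
    path = tmp_path / "m.png"
    mio.write_mask_image(path, mask)
    assert np.array_equal(mio.read_mask_image(path), mask)


def test_read_binarizes_gray_levels(tmp_path):
    import imageio.v3 as iio

    arr = np.array([[0, 128, 255], [7, 0, 1]], np.uint8)
    path = tmp_path / "g.png"
    iio.imwrite(path, arr)
    mask = mio.read_mask_image(path)
    assert mio.foreground_count(mask) == int(np.count_nonzero(arr))
    assert set(np.unique(mask)) <= {0, 255}


def test_read_all_zero_png(tmp_path):
    import imageio.v3 as iio

    path = tmp_path / "z.png"
    iio.imwrite(path, np.zeros((5, 5), np.uint8))
    assert mio.foreground_count(mio.read_mask_image(path)) == 0


def test_read_missing_file_raises(tmp_path):
    with pytest.raises(OSError):
        mio.read_mask_image(tmp_path / "nope.png")


# --- polygon rasterization -------------------------------------------------


def test_axis_aligned_square_is_100_pixels():
    mask = mio.polygon_to_mask([(10, 10), (20, 10), (20, 20), (10, 20)], 30, 30)
    assert mio.foreground_count(mask) == 100


def test_degenerate_collinear_polygon_is_empty():
    mask = mio.polygon_to_mask([(1, 1), (5, 5), (9, 9)], 12, 12)
    assert mio.foreground_count(mask) == 0


def test_circle_polygon_area_within_1pct():
    r, c = 50.0, (64.0, 64.0)
    th = np.linspace(0, 2 * math.pi, 64, endpoint=False)
    verts = np.column_stack([c[0] + r * np.cos(th), c[1] + r * np.sin(th)])
    count = mio.foreground_count(mio.polygon_to_mask(verts, 128, 128))
    assert abs(count - math.pi * r**2) / (math.pi * r**2) < 0.01


def test_too_few_vertices_raises():
    with pytest.raises(GeometryError):
        mio.polygon_to_mask([(0, 0), (5, 5)], 10, 10)


@pytest.mark.parametrize("seed", range(5))
def test_polygon_fill_matches_point_in_polygon_oracle(seed):
    """Pixel-center rasterization agrees with an independent geometric
    point-in-polygon test on random star-shaped polygons."""
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 10)
    angles = np.sort(rng.uniform(0, 2 * math.pi, n))
    radii = rng.uniform(5, 14, n)
    verts = np.column_stack(
        [15 + radii * np.cos(angles), 15 + radii * np.sin(angles)]
    )
    mask = mio.polygon_to_mask(verts, 30, 30)
    poly = Polygon(verts)
    xs, ys = np.meshgrid(np.arange(30) + 0.5, np.arange(30) + 0.5)
    oracle = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(30, 30)
    # boundary-grazing centers may differ either way; interior/exterior must agree
    disagree = (mask != 0) != oracle
    assert disagree.mean() < 0.01


# --- instance selection ----------------------------------------------------


def test_largest_instance_selected():
    a = square_mask(40, 40, 0, 0, 22)  # 484 px
    b = square_mask(40, 40, 0, 0, 29)  # 841 px
    chosen = mio.select_largest_instance({"fruit": [(a, 0.9), (b, 0.9)]}, "fruit")
    assert chosen is b


def test_confidence_threshold_excludes():
    a = square_mask(10, 10, 0, 0, 5)
    assert mio.select_largest_instance({"fruit": [(a, 0.2)]}, "fruit") is None
    assert mio.select_largest_instance({"fruit": [(a, 0.3)]}, "fruit") is a


def test_tie_breaks_area_then_confidence_then_order():
    a = square_mask(10, 10, 0, 0, 5)
    b = square_mask(10, 10, 5, 5, 5)
    assert mio.select_largest_instance({"m": [(a, 0.5), (b, 0.8)]}, "m") is b
    assert mio.select_largest_instance({"m": [(a, 0.8), (b, 0.8)]}, "m") is a


def test_selection_invariant_to_order():
    rng = np.random.default_rng(3)
    entries = [(mio.binarize(rng.integers(0, 2, (12, 12))), 0.5 + 0.1 * i) for i in range(4)]
    first = mio.select_largest_instance({"c": entries}, "c")
    reordered = mio.select_largest_instance({"c": entries[::-1]}, "c")
    assert np.array_equal(first, reordered)


# --- subtraction and IoU ---------------------------------------------------


@settings(max_examples=40, deadline=None, derandomize=True)
@given(body=small_masks, calyx=small_masks)
def test_subtraction_set_identity(body, calyx):
    result = mio.subtract_mask(body, calyx)
    inter = np.count_nonzero((body != 0) & (calyx != 0))
    assert mio.foreground_count(result) == mio.foreground_count(body) - inter
    assert not np.any((result != 0) & (calyx != 0))  # disjoint from calyx


def test_subtract_disjoint_and_superset():
    body = square_mask(20, 20, 0, 0, 8)
    far = square_mask(20, 20, 10, 10, 5)
    assert np.array_equal(mio.subtract_mask(body, far), body)
    cover = square_mask(20, 20, 0, 0, 20)
    assert mio.foreground_count(mio.subtract_mask(body, cover)) == 0


def test_subtract_dimension_mismatch():
    with pytest.raises(GeometryError):
        mio.subtract_mask(np.zeros((3, 3), np.uint8), np.zeros((4, 4), np.uint8))


def test_iou_cases():
    a = square_mask(20, 20, 0, 0, 10)  # 100 px
    sub = square_mask(20, 20, 0, 0, 10)
    sub[5:, :] = 0  # 50-px sub-mask
    empty = np.zeros((20, 20), np.uint8)
    assert mio.iou(a, a) == 1.0
    assert mio.iou(a, square_mask(20, 20, 10, 10, 5)) == 0.0
    assert mio.iou(a, sub) == 0.5
    assert mio.iou(empty, empty) == 1.0  # documented both-empty convention


@settings(max_examples=40, deadline=None, derandomize=True)
@given(a=small_masks, b=small_masks)
def test_iou_symmetric_and_bounded(a, b):
    assert mio.iou(a, b) == mio.iou(b, a)
    assert 0.0 <= mio.iou(a, b) <= 1.0


def test_mean_iou_arithmetic_and_permutation():
    identical = square_mask(20, 20, 0, 0, 10)
    half = identical.copy()
    half[5:, :] = 0
    disjoint = square_mask(20, 20, 10, 10, 5)
    pred = {"a": identical, "b": half, "c": disjoint}
    truth = {"a": identical, "b": identical, "c": identical}
    assert mio.mean_iou(pred, truth) == pytest.approx(0.5)
    shuffled = {k: pred[k] for k in ("c", "a", "b")}
    assert mio.mean_iou(shuffled, truth) == mio.mean_iou(pred, truth)
    with pytest.raises(ParameterError):
        mio.mean_iou({}, {})


def test_f1_per_class():
    truth = square_mask(20, 20, 0, 0, 10)
    half = truth.copy()
    half[5:, :] = 0
    empty = np.zeros_like(truth)
    scores = mio.f1_per_class(
        {"perfect": truth, "half": half, "miss": empty},
        {"perfect": truth, "half": truth, "miss": truth},
    )
    assert scores["perfect"].f1 == 1.0
    assert scores["half"].precision == 1.0
    assert scores["half"].recall == pytest.approx(0.5)
    assert scores["half"].f1 == pytest.approx(2 / 3)
    assert scores["miss"].f1 == 0.0


def test_segmentation_report_schema():
    m = square_mask(10, 10, 0, 0, 5)
    report = mio.segmentation_report({"fruit": m}, {"fruit": m})
    assert list(report["class"]) == ["fruit", "mIoU"]
    assert report.iloc[-1]["IoU"] == 1.0


def test_polygon_annotation_round_trip(tmp_path):
    polys = [
        ("fruit", np.array([[1.5, 2.0], [8.0, 2.0], [5.0, 9.0]])),
        ("marker", np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 4.0], [0.0, 4.0]])),
    ]
    path = tmp_path / "ann.txt"
    mio.write_polygon_annotations(path, polys)
    loaded = mio.read_polygon_annotations(path)
    assert [label for label, _ in loaded] == ["fruit", "marker"]
    for (_, orig), (_, back) in zip(polys, loaded):
        assert np.allclose(orig, back, atol=1e-4)
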