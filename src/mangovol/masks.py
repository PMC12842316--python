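"""Binary instance masks: I/O, rasterization, selection and quality metrics.

A mask is a 2D ``uint8`` array holding only the values 0 (background) and
255 (foreground), row-major with the origin at the top-left corner.  The
pixel at index ``(r, c)`` covers the unit square ``[r, r+1) x [c, c+1)`` and
has its center at ``(r + 0.5, c + 0.5)``; every rasterization rule in this
package tests pixel centers against the analytic shape.

Segmentation quality is scored pixelwise: per-class IoU, the unweighted
mean IoU over classes, and per-class precision/recall/F1 from TP/FP/FN
counts.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import GeometryError, MaskFormatError, ParameterError

FOREGROUND = 255
CLASS_LABELS = ("fruit", "calyx", "marker")

__all__ = [
    "FOREGROUND",
    "CLASS_LABELS",
    "binarize",
    "read_mask_image",
    "write_mask_image",
    "polygon_to_mask",
    "foreground_count",
    "select_largest_instance",
    "subtract_mask",
    "iou",
    "mean_iou",
    "confusion_counts",
    "f1_per_class",
    "segmentation_report",
    "read_polygon_annotations",
    "write_polygon_annotations",
    "ClassScore",
]


def binarize(array: np.ndarray) -> np.ndarray:
    """Map any array to the 0/255 mask convention: nonzero -> 255."""
    arr = np.asarray(array)
    if arr.ndim == 3:  # RGB(A): foreground where any channel is lit
        arr = np.any(arr != 0, axis=-1)
    if arr.ndim != 2:
        raise MaskFormatError(f"expected a 2D mask, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise MaskFormatError("mask must be at least 1x1")
    return np.where(arr != 0, FOREGROUND, 0).astype(np.uint8)


def read_mask_image(path) -> np.ndarray:
    """Read a PNG (or any imageio-readable image) as a binary mask.

    Any nonzero pixel becomes foreground (255).  Unreadable files raise the
    underlying I/O error; an image with no pixels raises MaskFormatError.
    """
    arr = iio.imread(path)
    if arr.size == 0:
        raise MaskFormatError(f"{path}: image decodes to zero pixels")
    return binarize(arr)


def write_mask_image(path, mask: np.ndarray) -> None:
    iio.imwrite(path, binarize(mask))


def polygon_to_mask(vertices, height: int, width: int) -> np.ndarray:
    """Rasterize a polygon with the even-odd rule at pixel centers.

    ``vertices`` is a sequence of ``(x, y)`` pairs in pixel coordinates
    (x = column, y = row).  A pixel is foreground iff its center
    ``(c + 0.5, r + 0.5)`` lies inside the polygon under even-odd
    (crossing-number) filling.  Zero-area polygons rasterize to the empty
    mask.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise GeometryError("polygon needs at least 3 (x, y) vertices")
    if height < 1 or width < 1:
        raise ParameterError("mask dimensions must be >= 1")
    xs = np.arange(width) + 0.5
    ys = np.arange(height) + 0.5
    parity = np.zeros((height, width), dtype=bool)
    for (ax, ay), (bx, by) in zip(v, np.roll(v, -1, axis=0)):
        if ay == by:
            continue
        crosses_row = (ay > ys) != (by > ys)
        x_at_row = ax + (ys - ay) * (bx - ax) / (by - ay)
        parity ^= crosses_row[:, None] & (xs[None, :] < x_at_row[:, None])
    return np.where(parity, FOREGROUND, 0).astype(np.uint8)


def foreground_count(mask: np.ndarray) -> int:
    return int(np.count_nonzero(mask))


def select_largest_instance(
    instances: Mapping[str, Sequence[tuple]],
    class_label: str,
    confidence_min: float = 0.3,
):
    """Keep the largest-area predicted mask of a class above a confidence cut.

    Among the instances of ``class_label`` whose confidence is at least
    ``confidence_min``, return the mask with the most foreground pixels.
    Ties break by higher confidence, then by input order.  Returns ``None``
    when nothing qualifies (absence is a value, not an error).
    """
    best = None
    best_key = None
    for idx, (mask, conf) in enumerate(instances.get(class_label, ())):
        if conf < confidence_min:
            continue
        key = (foreground_count(mask), conf, -idx)
        if best_key is None or key > best_key:
            best, best_key = mask, key
    return best


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise GeometryError(f"mask dimension mismatch: {a.shape} vs {b.shape}")


def subtract_mask(body: np.ndarray, calyx: np.ndarray) -> np.ndarray:
    """Foreground of ``body`` with the ``calyx`` pixels removed."""
    _check_same_shape(body, calyx)
    return np.where((body != 0) & (calyx == 0), FOREGROUND, 0).astype(np.uint8)


def union_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _check_same_shape(a, b)
    return np.where((a != 0) | (b != 0), FOREGROUND, 0).astype(np.uint8)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two masks.

    When both masks are empty the IoU is defined as 1.0: both predictions
    agree on total absence.  (Conventions differ across toolkits; this one
    avoids 0/0 and rewards correct negatives.)
    """
    _check_same_shape(a, b)
    fa, fb = a != 0, b != 0
    union = np.count_nonzero(fa | fb)
    if union == 0:
        return 1.0
    return np.count_nonzero(fa & fb) / union


def mean_iou(pred: Mapping[str, np.ndarray], truth: Mapping[str, np.ndarray]) -> float:
    """Unweighted mean of per-class IoU over the shared class set."""
    if not pred or set(pred) != set(truth):
        raise ParameterError("pred and truth must share a nonempty class set")
    return float(np.mean([iou(pred[c], truth[c]) for c in pred]))


def confusion_counts(
    pred: Mapping[str, np.ndarray], truth: Mapping[str, np.ndarray]
) -> dict[str, tuple[int, int, int]]:
    """Pixelwise (TP, FP, FN) per class."""
    if not pred or set(pred) != set(truth):
        raise ParameterError("pred and truth must share a nonempty class set")
    out = {}
    for c in pred:
        _check_same_shape(pred[c], truth[c])
        p, g = pred[c] != 0, truth[c] != 0
        out[c] = (
            int(np.count_nonzero(p & g)),
            int(np.count_nonzero(p & ~g)),
            int(np.count_nonzero(~p & g)),
        )
    return out


class ClassScore(NamedTuple):
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    iou: float


def f1_per_class(
    pred: Mapping[str, np.ndarray], truth: Mapping[str, np.ndarray]
) -> dict[str, ClassScore]:
    """Per-class precision, recall and F1 from pixelwise confusion counts.

    Precision (recall) is 0 when its denominator is 0; F1 is 0 when
    precision + recall is 0.
    """
    scores = {}
    for c, (tp, fp, fn) in confusion_counts(pred, truth).items():
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        scores[c] = ClassScore(tp, fp, fn, precision, recall, f1, iou(pred[c], truth[c]))
    return scores


def segmentation_report(
    pred: Mapping[str, np.ndarray], truth: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Tabular segmentation evaluation: one row per class plus an mIoU summary."""
    scores = f1_per_class(pred, truth)
    rows = [
        {
            "class": c,
            "TP": s.tp,
            "FP": s.fp,
            "FN": s.fn,
            "precision": s.precision,
            "recall": s.recall,
            "F1": s.f1,
            "IoU": s.iou,
        }
        for c, s in scores.items()
    ]
    miou = float(np.mean([s.iou for s in scores.values()]))
    rows.append(
        {
            "class": "mIoU",
            "TP": np.nan,
            "FP": np.nan,
            "FN": np.nan,
            "precision": np.nan,
            "recall": np.nan,
            "F1": np.nan,
            "IoU": miou,
        }
    )
    return pd.DataFrame(rows)


def write_polygon_annotations(path, polygons: Iterable[tuple[str, np.ndarray]]) -> None:
    """One object per line: ``class_label x1 y1 x2 y2 ...`` (pixel units)."""
    with open(path, "w") as fh:
        for label, verts in polygons:
            flat = " ".join(f"{v:.4f}" for xy in np.asarray(verts, float) for v in xy)
            fh.write(f"{label} {flat}\n")


def read_polygon_annotations(path) -> list[tuple[str, np.ndarray]]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            label, coords = parts[0], list(map(float, parts[1:]))
            if len(coords) % 2:
                raise MaskFormatError(f"{path}: odd coordinate count for {label!r}")
            out.append((label, np.asarray(coords, float).reshape(-1, 2)))
    return out
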