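"""Parametric renderer of composite-fruit scenes with analytic ground truth.

Stands in for the camera and the neural segmenter: each scene is a triple of
binary class masks (fruit body, calyx, fiducial marker) for one of two
orthogonal views, together with the exact analytic volume of the generating
ellipsoid.

Model
-----
A fruit body is a triaxial ellipsoid with semi-axes ``(semi_axis_h,
semi_axis_w, semi_axis_d)`` in cm — vertical, lateral and depth.  The side
view projects the (h, d) plane; the bottom view projects the (w, d) plane.
The calyx — the lobed leafy structure that makes this fruit hard for naive
silhouette models — is modeled as ``calyx_lobes`` overlapping disks whose
centers sit on the body silhouette (offset outward by ``calyx_protrusion``)
on the side facing the right image edge; calyx pixels are rendered outside
the body so the class masks are disjoint.  In the bottom view the lobes
point toward the camera and project inside the body silhouette, so the
bottom-view calyx mask is empty.  A square fiducial marker of known
physical side (default 30 mm) provides per-image metric scale.

Rasterization rule: a pixel is foreground iff its center lies strictly
inside the analytic shape, which keeps rasterized areas asymptotically
unbiased as resolution grows.  All randomness flows through explicit seeds;
there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import GeometryError, ParameterError
from .masks import FOREGROUND, write_mask_image, write_polygon_annotations

VIEWS = ("side", "bottom")

__all__ = [
    "FruitSpec",
    "SceneSpec",
    "RenderedScene",
    "make_fruit_population",
    "default_scene",
    "render_scene",
    "render_views",
    "write_scenes",
    "read_manifest",
    "scene_polygons",
    "write_scene_annotations",
]


@dataclass(frozen=True)
class FruitSpec:
    """Generative description of one fruit (lengths in cm, mass in g)."""

    id: str
    semi_axis_h: float
    semi_axis_w: float
    semi_axis_d: float
    calyx_lobes: int = 0
    calyx_lobe_radius: float = 0.0
    calyx_protrusion: float = 0.0
    mass: float = float("nan")

    def __post_init__(self):
        if min(self.semi_axis_h, self.semi_axis_w, self.semi_axis_d) <= 0:
            raise ParameterError("all semi-axes must be positive")
        if self.calyx_lobes < 0 or self.calyx_lobe_radius < 0 or self.calyx_protrusion < 0:
            raise ParameterError("calyx fields must be >= 0")

    @property
    def volume(self) -> float:
        """Exact ellipsoid volume (4/3)*pi*a*b*c in cm^3, independent of rendering."""
        return 4.0 / 3.0 * math.pi * self.semi_axis_h * self.semi_axis_w * self.semi_axis_d


@dataclass(frozen=True)
class SceneSpec:
    """Imaging geometry for one view: canvas, scale and element placement."""

    view: str
    image_height: int
    image_width: int
    mm_per_px: float
    fruit_center: tuple[float, float]  # (row, col), sub-pixel allowed
    marker_origin: tuple[int, int] = (0, 0)  # top-left (row, col)
    marker_side_mm: float = 30.0

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ParameterError(f"view must be one of {VIEWS}")
        if self.mm_per_px <= 0 or self.marker_side_mm <= 0:
            raise ParameterError("scales must be positive")
        if self.image_height < 1 or self.image_width < 1:
            raise ParameterError("image dimensions must be >= 1")

    @property
    def marker_side_px(self) -> float:
        return self.marker_side_mm / self.mm_per_px

    @property
    def px_per_cm(self) -> float:
        return 10.0 / self.mm_per_px


@dataclass(frozen=True)
class RenderedScene:
    fruit_mask: np.ndarray
    calyx_mask: np.ndarray
    marker_mask: np.ndarray
    true_volume: float
    fruit: FruitSpec
    scene: SceneSpec


def make_fruit_population(
    n: int,
    volume_mean: float = 51.52,
    volume_sd: float = 10.61,
    aspect_jitter: float = 0.1,
    calyx_scale: float = 1.0,
    seed: int = 0,
) -> list[FruitSpec]:
    """Draw ``n`` fruit specs with volumes from a truncated-at-zero normal.

    The default mean/SD reproduce the measured population statistics of the
    cleaned reference dataset (mean 51.52 cm^3, SD 10.61 cm^3).  Each volume
    V is split into three semi-axes ``r*(1+eps_i)`` with
    ``eps_i ~ U(-aspect_jitter, +aspect_jitter)``, renormalized so the
    analytic volume stays exactly V.  Mass is assigned so density lies in
    [1.00, 1.15] g/cm^3 — the post-filter physical range.  ``calyx_scale``
    scales the lobe radius/protrusion defaults (0 disables the calyx).
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if volume_mean <= 0:
        raise ParameterError("volume_mean must be positive")
    if volume_sd < 0 or aspect_jitter < 0 or calyx_scale < 0:
        raise ParameterError("volume_sd, aspect_jitter and calyx_scale must be >= 0")

    rng = np.random.default_rng(seed)
    if volume_sd == 0:
        volumes = np.full(n, volume_mean)
    else:
        volumes = stats.truncnorm.rvs(
            a=-volume_mean / volume_sd, b=np.inf,
            loc=volume_mean, scale=volume_sd, size=n, random_state=rng,
        )

    fruits = []
    for i, vol in enumerate(volumes):
        r = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
        eps = rng.uniform(-aspect_jitter, aspect_jitter, size=3)
        axes = r * (1.0 + eps)
        axes /= np.prod(axes / r) ** (1.0 / 3.0)  # renormalize: volume preserved
        # depth is the smallest axis: the dimension-assignment convention
        # (larger side -> h or w, smaller -> depth) then recovers the
        # generating axes, as it does for a consistently posed fruit
        axes = np.sort(axes)[::-1]
        axes[:2] = rng.permutation(axes[:2])  # h vs w order stays random
        density = rng.uniform(1.00, 1.15)
        if calyx_scale > 0:
            lobes = int(rng.integers(4, 8))
            lobe_radius = 0.55 * calyx_scale * (1.0 + rng.uniform(-0.3, 0.3))
            protrusion = 0.35 * calyx_scale * (1.0 + rng.uniform(-0.3, 0.3))
        else:
            lobes, lobe_radius, protrusion = 0, 0.0, 0.0
        fruits.append(
            FruitSpec(
                id=f"fruit{i:04d}",
                semi_axis_h=float(axes[0]),
                semi_axis_w=float(axes[1]),
                semi_axis_d=float(axes[2]),
                calyx_lobes=lobes,
                calyx_lobe_radius=float(lobe_radius),
                calyx_protrusion=float(protrusion),
                mass=float(density * vol),
            )
        )
    return fruits


def make_triaxial_population(
    n: int,
    volume_mean: float,
    volume_sd: float = 0.0,
    ratios: tuple[float, float, float] = (1.25, 1.0, 0.8),
    axis_jitter: float = 0.03,
    seed: int = 0,
) -> list[FruitSpec]:
    """Strongly triaxial fruit specs with well-separated axes.

    The minimum-area rotated rectangle has a flat angular objective on
    near-circular silhouettes, so its side lengths are ill-conditioned
    there (the fitted angle can flip under sub-pixel noise while the area
    barely changes).  Shape-descriptor stability studies therefore use
    populations whose axis ratios are separated well beyond that
    degeneracy; ``ratios`` fixes the (h, w, d) proportions (descending, so
    the depth axis stays smallest) and ``axis_jitter`` adds small
    per-axis variation.  Volumes are exact: the jittered axes are
    renormalized to the drawn volume.
    """
    if n < 1 or volume_mean <= 0:
        raise ParameterError("n and volume_mean must be positive")
    if not ratios[0] >= ratios[1] >= ratios[2] > 0:
        raise ParameterError("ratios must be descending and positive")
    rng = np.random.default_rng(seed)
    base = np.asarray(ratios, float)
    base /= np.prod(base) ** (1.0 / 3.0)  # unit-volume proportions
    if volume_sd == 0:
        volumes = np.full(n, volume_mean)
    else:
        volumes = stats.truncnorm.rvs(
            a=-volume_mean / volume_sd, b=np.inf,
            loc=volume_mean, scale=volume_sd, size=n, random_state=rng,
        )
    fruits = []
    for i, vol in enumerate(volumes):
        r = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
        axes = r * base * (1.0 + rng.uniform(-axis_jitter, axis_jitter, 3))
        axes *= (r**3 / np.prod(axes)) ** (1.0 / 3.0)
        fruits.append(
            FruitSpec(
                id=f"fruit{i:04d}",
                semi_axis_h=float(axes[0]),
                semi_axis_w=float(axes[1]),
                semi_axis_d=float(axes[2]),
                mass=float(rng.uniform(1.00, 1.15) * vol),
            )
        )
    return fruits


def _projection_semi_axes(fruit: FruitSpec, view: str, px_per_cm: float):
    """(vertical, horizontal) projected semi-axes in px for a view."""
    if view == "side":
        return fruit.semi_axis_h * px_per_cm, fruit.semi_axis_d * px_per_cm
    return fruit.semi_axis_d * px_per_cm, fruit.semi_axis_w * px_per_cm


def _calyx_spill_px(fruit: FruitSpec, px_per_cm: float) -> float:
    if fruit.calyx_lobes == 0:
        return 0.0
    return (fruit.calyx_protrusion + fruit.calyx_lobe_radius) * px_per_cm


def default_scene(
    fruit: FruitSpec,
    view: str,
    mm_per_px: float,
    marker_side_mm: float = 30.0,
    margin_px: int = 12,
    rng: np.random.Generator | None = None,
) -> SceneSpec:
    """Compact canvas with the marker top-left and the fruit to its right.

    When ``rng`` is given, the fruit center receives a sub-pixel jitter so
    rasterization phases vary across a population (keeps aggregate feature
    errors unbiased).
    """
    px_per_cm = 10.0 / mm_per_px
    half_r, half_c = _projection_semi_axes(fruit, view, px_per_cm)
    spill = _calyx_spill_px(fruit, px_per_cm) if view == "side" else 0.0
    marker_px = int(math.ceil(marker_side_mm / mm_per_px))
    # calyx lobes can spill vertically as well as toward the right edge
    fruit_h = int(math.ceil(2 * half_r + 2 * spill)) + 4
    fruit_w = int(math.ceil(2 * half_c + spill)) + 4
    height = 2 * margin_px + max(marker_px, fruit_h)
    width = 3 * margin_px + marker_px + fruit_w
    jitter = rng.random(2) if rng is not None else np.zeros(2)
    center = (
        height / 2.0 + float(jitter[0]),
        2 * margin_px + marker_px + half_c + 2 + float(jitter[1]),
    )
    return SceneSpec(
        view=view,
        image_height=height,
        image_width=width,
        mm_per_px=mm_per_px,
        fruit_center=center,
        marker_origin=(margin_px, margin_px),
        marker_side_mm=marker_side_mm,
    )


def _ellipse_mask(height, width, center_rc, semi_r, semi_c) -> np.ndarray:
    rr = (np.arange(height) + 0.5 - center_rc[0]) / semi_r
    cc = (np.arange(width) + 0.5 - center_rc[1]) / semi_c
    return (rr[:, None] ** 2 + cc[None, :] ** 2) < 1.0


def _disk_mask(height, width, center_rc, radius) -> np.ndarray:
    rr = np.arange(height) + 0.5 - center_rc[0]
    cc = np.arange(width) + 0.5 - center_rc[1]
    return (rr[:, None] ** 2 + cc[None, :] ** 2) < radius**2


def _calyx_lobe_centers(fruit: FruitSpec, scene: SceneSpec):
    """Lobe disk centers (row, col) in px, on the right-facing silhouette."""
    half_r, half_c = _projection_semi_axes(fruit, scene.view, scene.px_per_cm)
    k = fruit.calyx_lobes
    thetas = np.linspace(-0.9, 0.9, k) if k > 1 else np.array([0.0])
    protrusion_px = fruit.calyx_protrusion * scene.px_per_cm
    centers = []
    for th in thetas:
        # silhouette point, x to the right; outward normal of the ellipse
        dx, dy = half_c * math.cos(th), half_r * math.sin(th)
        nx, ny = math.cos(th) / half_c, math.sin(th) / half_r
        norm = math.hypot(nx, ny)
        centers.append(
            (
                scene.fruit_center[0] + dy + protrusion_px * ny / norm,
                scene.fruit_center[1] + dx + protrusion_px * nx / norm,
            )
        )
    return centers


def render_scene(fruit: FruitSpec, scene: SceneSpec) -> RenderedScene:
    """Rasterize one view of one fruit into the three class masks.

    Raises GeometryError naming the offending element when the fruit
    projection (including calyx spill) or the marker leaves the canvas, or
    when marker and fruit overlap.
    """
    h, w = scene.image_height, scene.image_width
    px_per_cm = scene.px_per_cm
    half_r, half_c = _projection_semi_axes(fruit, scene.view, px_per_cm)
    cr, cc = scene.fruit_center

    if cr - half_r < 0 or cr + half_r > h or cc - half_c < 0 or cc + half_c > w:
        raise GeometryError(f"fruit {fruit.id!r} projection out of bounds")
    if scene.view == "side" and fruit.calyx_lobes > 0 and fruit.calyx_lobe_radius > 0:
        radius_px = fruit.calyx_lobe_radius * px_per_cm
        for lr, lc in _calyx_lobe_centers(fruit, scene):
            if lr - radius_px < 0 or lr + radius_px > h or lc - radius_px < 0 or lc + radius_px > w:
                raise GeometryError(f"calyx of fruit {fruit.id!r} out of bounds")
    r0, c0 = scene.marker_origin
    side_px = scene.marker_side_px
    if r0 < 0 or c0 < 0 or r0 + side_px > h or c0 + side_px > w:
        raise GeometryError("marker out of bounds")

    body = _ellipse_mask(h, w, (cr, cc), half_r, half_c)

    calyx = np.zeros_like(body)
    if scene.view == "side" and fruit.calyx_lobes > 0 and fruit.calyx_lobe_radius > 0:
        radius_px = fruit.calyx_lobe_radius * px_per_cm
        for center in _calyx_lobe_centers(fruit, scene):
            calyx |= _disk_mask(h, w, center, radius_px)
        calyx &= ~body  # calyx rendered strictly outside the body

    # marker: pixel centers (r+0.5) inside [r0, r0+side) on both axes
    rows = (np.arange(h) + 0.5 >= r0) & (np.arange(h) + 0.5 < r0 + side_px)
    cols = (np.arange(w) + 0.5 >= c0) & (np.arange(w) + 0.5 < c0 + side_px)
    marker = rows[:, None] & cols[None, :]

    if np.any(marker & (body | calyx)):
        raise GeometryError(f"marker overlaps fruit {fruit.id!r}")

    to_mask = lambda b: np.where(b, FOREGROUND, 0).astype(np.uint8)
    return RenderedScene(
        fruit_mask=to_mask(body),
        calyx_mask=to_mask(calyx),
        marker_mask=to_mask(marker),
        true_volume=fruit.volume,
        fruit=fruit,
        scene=scene,
    )


def render_views(
    fruit: FruitSpec,
    mm_per_px: float,
    marker_side_mm: float = 30.0,
    rng: np.random.Generator | None = None,
) -> tuple[RenderedScene, RenderedScene]:
    """Render the side and bottom view of a fruit with default scene layout."""
    side = render_scene(
        fruit, default_scene(fruit, "side", mm_per_px, marker_side_mm, rng=rng)
    )
    bottom = render_scene(
        fruit, default_scene(fruit, "bottom", mm_per_px, marker_side_mm, rng=rng)
    )
    return side, bottom


def write_scenes(scenes, outdir) -> pd.DataFrame:
    """Persist scenes as per-class PNGs plus a ``scenes.csv`` manifest.

    Files are named ``{id}_{view}_{class}.png``.  The manifest has columns
    id, view, mm_per_px, true_volume, mass (one row per view).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sc in scenes:
        stem = f"{sc.fruit.id}_{sc.scene.view}"
        for cls, mask in (
            ("fruit", sc.fruit_mask),
            ("calyx", sc.calyx_mask),
            ("marker", sc.marker_mask),
        ):
            write_mask_image(outdir / f"{stem}_{cls}.png", mask)
        rows.append(
            {
                "id": sc.fruit.id,
                "view": sc.scene.view,
                "mm_per_px": sc.scene.mm_per_px,
                "true_volume": sc.true_volume,
                "mass": sc.fruit.mass,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "scenes.csv", index=False)
    return manifest


def read_manifest(outdir) -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / "scenes.csv")


def scene_polygons(fruit: FruitSpec, scene: SceneSpec, n_vertices: int = 128):
    """Polygonal annotations of a scene: (class_label, (x, y) vertices).

    The body and each calyx lobe are approximated by inscribed
    ``n_vertices``-gons; the marker is an exact square.  Intended for
    round-trip testing against ``masks.polygon_to_mask``.
    """
    half_r, half_c = _projection_semi_axes(fruit, scene.view, scene.px_per_cm)
    cr, cc = scene.fruit_center
    th = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    out = [("fruit", np.column_stack([cc + half_c * np.cos(th), cr + half_r * np.sin(th)]))]
    if scene.view == "side" and fruit.calyx_lobes > 0 and fruit.calyx_lobe_radius > 0:
        radius_px = fruit.calyx_lobe_radius * scene.px_per_cm
        for lr, lc in _calyx_lobe_centers(fruit, scene):
            out.append(
                ("calyx", np.column_stack([lc + radius_px * np.cos(th), lr + radius_px * np.sin(th)]))
            )
    r0, c0 = scene.marker_origin
    s = scene.marker_side_px
    out.append(
        ("marker", np.array([[c0, r0], [c0 + s, r0], [c0 + s, r0 + s], [c0, r0 + s]], float))
    )
    return out


def write_scene_annotations(path, fruit: FruitSpec, scene: SceneSpec, n_vertices: int = 128):
    write_polygon_annotations(path, scene_polygons(fruit, scene, n_vertices))
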