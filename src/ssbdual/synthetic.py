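"""Synthetic scenes: phantoms, animal scenes with labels, optical panoramas.

Everything the pipeline consumes can be generated here with known ground
truth.  Three families of input are emulated:

* **Phantom scenes** — a microtest tube (< 8 mm diameter) holding 0.25 g of
  reagent at one of the study concentrations (0.3, 0.2, 0.1, 0.01,
  0.005 emu/g), voxelised as a cylinder at a configurable probe standoff
  (31-65 mm).  Total magnetism is conserved exactly across voxelisation.
* **Animal scenes** — either a back tumor or a five-lobe liver fan; every
  tissue voxel carries a weak paramagnetic background (red blood cells
  etc.), and at 24 h after injection labelled-positive regions additionally
  carry nanoparticle uptake.  At 0 h (pre-injection) there is background
  only.  Geometry is schematic (convex lobes in a fan), not anatomical.
* **Optical panoramas** — per-line camera strips rendering the ground-truth
  contours (brown tube circle, blue dashed tumor outline, grey lobe edges)
  wide enough that the central-2/3 mosaic crop still tiles the scan swath.

Per-lobe uptake and background defaults are modelling choices pinned to the
display calibration of the forward model (see docs/methods.md), chosen so
positive lobes integrate above and negative lobes below 0.10 Volt*mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .classify import NEGATIVE, POSITIVE, LobeROI
from .forward import Scene, cylinder_voxels
from .imaging import ScanPlan
from .units import sample_magnetism

__all__ = [
    "PhantomSpec",
    "AnimalSceneSpec",
    "make_phantom_scene",
    "make_animal_scene",
    "make_liver_scene",
    "make_back_tumor_scene",
    "make_separated_lobe_scene",
    "make_lobe_dataset",
    "make_optical_panoramas",
    "STUDY_CONCENTRATIONS",
]

#: Reagent concentrations used throughout the phantom study, emu/g.
STUDY_CONCENTRATIONS = (0.3, 0.2, 0.1, 0.01, 0.005)

#: Nanoparticle uptake per labelled-positive region at 24 h, emu.  About
#: 0.06% of the injected 0.27 emu dose accumulating per tumor site; under the
#: default display calibration this puts positive-lobe integrals of I well
#: above the 0.10 Volt*mm^2 criterion.
DEFAULT_LOBE_UPTAKE = 1.5e-4

#: Weak paramagnetic tissue background, emu per 5 mm tissue voxel; sets the
#: 0 h signal floor to a small fraction (~10%) of the 24 h level.
DEFAULT_BACKGROUND_LEVEL = 3.0e-7

#: Depth of the tissue layer below the probe during an animal scan, mm.
TISSUE_DEPTH = 35.0
#: Depth of tumor uptake blobs (slightly shallower than the tissue layer), mm.
UPTAKE_DEPTH = 32.0
#: Depth of separated lobes laid out flat for the ex vivo examination, mm.
EX_VIVO_DEPTH = 32.0


@dataclass(frozen=True)
class PhantomSpec:
    """A reagent-filled microtest tube below the probe."""

    concentration: float = 0.3  # emu/g
    fill_weight: float = 0.25  # g
    tube_diameter: float = 6.0  # mm, must be < 8 (early-stage tumor size)
    probe_to_reagent: float = 31.0  # mm
    voxel_size: float = 1.0  # mm
    center_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.tube_diameter < 8.0:
            raise ValueError("tube_diameter must be in (0, 8) mm")
        if self.concentration < 0 or self.fill_weight <= 0:
            raise ValueError("concentration >= 0 and fill_weight > 0 required")
        if self.probe_to_reagent <= 0 or self.voxel_size <= 0:
            raise ValueError("probe_to_reagent and voxel_size must be > 0")

    @property
    def magnetism(self) -> float:
        return sample_magnetism(self.concentration, self.fill_weight)


@dataclass(frozen=True)
class AnimalSceneSpec:
    """A schematic animal scene: back tumor or five-lobe liver.

    ``labels`` gives the per-region staining ground truth (one entry for a
    back tumor, ``n_lobes`` for a liver); ``timepoint`` "0h" means
    pre-injection (background only), "24h" means uptake present in
    labelled-positive regions.
    """

    kind: str = "liver"  # "liver" | "back_tumor"
    n_lobes: int = 5
    labels: tuple[str, ...] = (POSITIVE, POSITIVE, POSITIVE, POSITIVE, NEGATIVE)
    timepoint: str = "24h"  # "0h" | "24h"
    lobe_uptake: float = DEFAULT_LOBE_UPTAKE  # emu per positive region
    background_level: float = DEFAULT_BACKGROUND_LEVEL  # emu per tissue voxel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("liver", "back_tumor"):
            raise ValueError("kind must be 'liver' or 'back_tumor'")
        n_regions = self.n_lobes if self.kind == "liver" else 1
        if len(self.labels) != n_regions:
            raise ValueError(f"need {n_regions} labels, got {len(self.labels)}")
        if any(lab not in (POSITIVE, NEGATIVE) for lab in self.labels):
            raise ValueError("labels must be 'positive'/'negative'")
        if self.timepoint not in ("0h", "24h"):
            raise ValueError("timepoint must be '0h' or '24h'")
        if self.background_level < 0 or self.lobe_uptake < 0:
            raise ValueError("background_level and lobe_uptake must be >= 0")


def make_phantom_scene(spec: PhantomSpec) -> Scene:
    """Voxelise one phantom tube; ground truth is the tube's top-view circle."""
    volume = spec.fill_weight * 1000.0  # g -> mm^3 at unit density
    pos = cylinder_voxels(
        spec.tube_diameter,
        volume,
        spec.voxel_size,
        top_z=-spec.probe_to_reagent,
        center_xy=spec.center_xy,
    )
    total = spec.magnetism
    mag = np.full(len(pos), total / len(pos))
    theta = np.linspace(0.0, 2.0 * np.pi, 65)
    circle = np.stack(
        [
            spec.center_xy[0] + spec.tube_diameter / 2.0 * np.cos(theta),
            spec.center_xy[1] + spec.tube_diameter / 2.0 * np.sin(theta),
        ],
        axis=1,
    )
    return Scene(pos, mag, ground_truth={"tube": circle})


# ---------------------------------------------------------------------------
# animal scenes
# ---------------------------------------------------------------------------


def _fan_lobes(n_lobes: int) -> list[np.ndarray]:
    """Five (or n) convex wedge polygons fanning over the upper half plane."""
    polys = []
    r = 32.0
    angles = np.linspace(np.pi * 0.05, np.pi * 0.95, n_lobes + 1)
    apex = np.array([0.0, -6.0])
    for i in range(n_lobes):
        a0, a1 = angles[i], angles[i + 1]
        mid = 0.5 * (a0 + a1)
        poly = np.array(
            [
                apex,
                [r * np.cos(a0), r * np.sin(a0) - 6.0],
                [r * np.cos(mid), r * np.sin(mid) - 6.0],
                [r * np.cos(a1), r * np.sin(a1) - 6.0],
                apex,
            ]
        )
        polys.append(poly)
    return polys


def _grid_points_in(poly: Polygon, spacing: float) -> np.ndarray:
    x0, y0, x1, y1 = poly.bounds
    xs = np.arange(x0 + spacing / 2.0, x1, spacing)
    ys = np.arange(y0 + spacing / 2.0, y1, spacing)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
    return np.stack([gx.ravel()[inside], gy.ravel()[inside]], axis=1)


def _uptake_blob(
    center: np.ndarray, radius: float, total: float, rng: np.random.Generator,
    region: Polygon,
) -> tuple[np.ndarray, np.ndarray]:
    """2 mm voxels in a jittered disk inside ``region``, sharing ``total`` emu."""
    jitter = rng.uniform(-2.0, 2.0, size=2)
    c = center + jitter
    disk = shapely.Point(c).buffer(radius).intersection(region.buffer(-1.0))
    if disk.is_empty:  # jitter pushed the blob out; fall back to the centroid
        disk = shapely.Point(center).buffer(radius).intersection(region)
    xy = _grid_points_in(disk, 2.0)
    if len(xy) == 0:
        xy = np.array([c])
    pos = np.column_stack([xy, np.full(len(xy), -UPTAKE_DEPTH)])
    return pos, np.full(len(pos), total / len(pos))


def make_animal_scene(spec: AnimalSceneSpec) -> tuple[Scene, list[LobeROI]]:
    """Build a back-tumor or liver scene plus its ROI list.

    The tissue background fills the body outline (an ellipse) as one 5 mm
    voxel layer at ``TISSUE_DEPTH``; at 24 h each positive region receives an
    uptake blob (seeded placement jitter) at ``UPTAKE_DEPTH``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "liver":
        region_polys = _fan_lobes(spec.n_lobes)
        names = [f"lobe_{i + 1}" for i in range(spec.n_lobes)]
    else:
        theta = np.linspace(0, 2 * np.pi, 41)
        tumor = np.stack([9.0 * np.cos(theta), 7.0 * np.sin(theta) + 5.0], axis=1)
        region_polys = [tumor]
        names = ["tumor"]

    theta = np.linspace(0, 2 * np.pi, 73)
    body = np.stack([45.0 * np.cos(theta), 38.0 * np.sin(theta)], axis=1)
    body_poly = Polygon(body)

    pos_list = []
    mag_list = []
    if spec.background_level > 0:
        bg_xy = _grid_points_in(body_poly, 5.0)
        pos_list.append(
            np.column_stack([bg_xy, np.full(len(bg_xy), -TISSUE_DEPTH)])
        )
        mag_list.append(np.full(len(bg_xy), spec.background_level))

    rois = []
    for name, poly, label in zip(names, region_polys, spec.labels):
        shape = Polygon(poly)
        rois.append(LobeROI(roi_id=name, polygon=poly, true_label=label))
        if spec.timepoint == "24h" and label == POSITIVE and spec.lobe_uptake > 0:
            centroid = np.asarray(shape.centroid.coords[0])
            p, m = _uptake_blob(centroid, 7.0, spec.lobe_uptake, rng, shape)
            pos_list.append(p)
            mag_list.append(m)

    positions = np.concatenate(pos_list) if pos_list else np.empty((0, 3))
    magnetism = np.concatenate(mag_list) if mag_list else np.empty((0,))
    ground_truth = {name: poly for name, poly in zip(names, region_polys)}
    ground_truth["body"] = body
    labels = {name: lab for name, lab in zip(names, spec.labels)}
    return Scene(positions, magnetism, ground_truth=ground_truth, labels=labels), rois


def make_liver_scene(spec: AnimalSceneSpec) -> tuple[Scene, list[LobeROI]]:
    """Five-lobe liver scene (see ``make_animal_scene``)."""
    if spec.kind != "liver":
        raise ValueError("make_liver_scene requires kind='liver'")
    return make_animal_scene(spec)


def make_back_tumor_scene(spec: AnimalSceneSpec) -> tuple[Scene, list[LobeROI]]:
    """Single back-tumor scene (see ``make_animal_scene``)."""
    if spec.kind != "back_tumor":
        raise ValueError("make_back_tumor_scene requires kind='back_tumor'")
    return make_animal_scene(spec)


def make_separated_lobe_scene(
    spec: AnimalSceneSpec,
    spacing: float = 55.0,
    depth: float = EX_VIVO_DEPTH,
) -> tuple[Scene, list[LobeROI]]:
    """Excised liver lobes laid out in a row at one common standoff.

    Emulates the ex vivo examination: after fixation the lobes are separated
    and scanned side by side, each at the same distance from the probe, so
    per-lobe quantification is free of the stacked-organ depth confound and
    of cross-talk between adjacent lobes (the gradiometer response width is
    comparable to the source depth, so in situ neighbours bleed into each
    other).  Uptake follows the labels exactly as in the in vivo scene; each
    lobe keeps a weak paramagnetic tissue background.
    """
    if spec.kind != "liver":
        raise ValueError("separated-lobe layout requires kind='liver'")
    rng = np.random.default_rng(spec.seed + 1)  # independent ex vivo handling
    lobes = _fan_lobes(spec.n_lobes)
    pos_list, mag_list, rois = [], [], []
    ground_truth = {}
    for i, (poly, label) in enumerate(zip(lobes, spec.labels)):
        shape = Polygon(poly)
        centroid = np.asarray(shape.centroid.coords[0])
        offset = np.array([(i - (spec.n_lobes - 1) / 2.0) * spacing, 0.0]) - centroid
        moved = np.asarray(poly, dtype=float) + offset
        moved_shape = Polygon(moved)
        name = f"lobe_{i + 1}"
        ground_truth[name] = moved
        rois.append(LobeROI(roi_id=name, polygon=moved, true_label=label))
        if spec.background_level > 0:
            bg_xy = _grid_points_in(moved_shape, 5.0)
            if len(bg_xy):
                pos_list.append(np.column_stack([bg_xy, np.full(len(bg_xy), -depth)]))
                mag_list.append(np.full(len(bg_xy), spec.background_level))
        if spec.timepoint == "24h" and label == POSITIVE and spec.lobe_uptake > 0:
            c = np.asarray(moved_shape.centroid.coords[0])
            p, m = _uptake_blob(c, 7.0, spec.lobe_uptake, rng, moved_shape)
            p[:, 2] = -depth
            pos_list.append(p)
            mag_list.append(m)
    positions = np.concatenate(pos_list) if pos_list else np.empty((0, 3))
    magnetism = np.concatenate(mag_list) if mag_list else np.empty((0,))
    labels = {r.roi_id: r.true_label for r in rois}
    scene = Scene(positions, magnetism, ground_truth=ground_truth, labels=labels)
    return scene, rois


# ---------------------------------------------------------------------------
# statistical lobe dataset (classifier tests without the physics)
# ---------------------------------------------------------------------------


def make_lobe_dataset(
    n_rats: int,
    separation: float = 1.0,
    sigma: float = 0.25,
    boundary: float = 0.10,
    p_positive: float = 0.5,
    n_lobes: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated per-lobe integrals of I with staining labels.

    Integrals are lognormal around the generating ``boundary``: positive
    lobes centred at ``boundary * exp(+separation/2)``, negative at
    ``boundary * exp(-separation/2)``, both with log-scale spread ``sigma``.
    ``separation`` (in log units) controls class overlap: large values give
    perfectly separable classes, zero gives indistinguishable ones.
    """
    if n_rats < 1:
        raise ValueError("n_rats must be >= 1")
    if sigma < 0 or not 0 <= p_positive <= 1:
        raise ValueError("sigma >= 0 and 0 <= p_positive <= 1 required")
    rng = np.random.default_rng(seed)
    n = n_rats * n_lobes
    positive = rng.random(n) < p_positive
    mu = np.log(boundary) + np.where(positive, separation / 2.0, -separation / 2.0)
    integrals = np.exp(rng.normal(mu, sigma))
    return pd.DataFrame(
        {
            "rat": np.repeat(np.arange(1, n_rats + 1), n_lobes),
            "lobe": np.tile(np.arange(1, n_lobes + 1), n_rats),
            "integral_volt_mm2": integrals,
            "stain_label": np.where(positive, POSITIVE, NEGATIVE),
        }
    )


# ---------------------------------------------------------------------------
# optical panoramas
# ---------------------------------------------------------------------------

_BACKGROUND_RGB = (0.93, 0.91, 0.86)
_STYLES = {
    "tube": {"rgb": (0.55, 0.33, 0.12), "dash": None},  # brown circle
    "tumor": {"rgb": (0.15, 0.25, 0.85), "dash": (4.0, 3.0)},  # blue dotted
}
_DEFAULT_STYLE = {"rgb": (0.45, 0.45, 0.45), "dash": None}  # grey outlines


def make_optical_panoramas(
    scene: Scene,
    plan: ScanPlan,
    mm_per_pixel: float = 0.5,
    line_width: float = 1.0,
) -> list[np.ndarray]:
    """Render one panorama strip per scan line showing ground-truth contours.

    Strips are (across_track, along_track, 3) RGB arrays 1.5 line intervals
    wide, so the central-2/3 mosaic crop tiles the swath exactly.  Contours
    are drawn as outlines: brown for tube circles, blue dashed for tumor
    outlines, grey otherwise.
    """
    w_px = 3.0 * plan.line_interval / (2.0 * mm_per_pixel)
    if abs(w_px - round(w_px)) > 1e-9:
        raise ValueError(
            "strip width 1.5 * line_interval must be an integer number of pixels"
        )
    w_px = int(round(w_px))
    along0 = plan.x_start - plan.step / 2.0
    along1 = plan.x_end + plan.step / 2.0
    n_along = int(round((along1 - along0) / mm_per_pixel))
    xs = along0 + (np.arange(n_along) + 0.5) * mm_per_pixel

    outlines = []
    for name, poly in scene.ground_truth.items():
        if name == "body":
            continue
        style = _STYLES.get(name.split("_")[0], _DEFAULT_STYLE)
        ring = Polygon(np.asarray(poly, dtype=float)).exterior
        line = shapely.LineString(ring)
        shapely.prepare(line)
        outlines.append((line, style))

    strips = []
    half_w = line_width / 2.0
    for i in range(plan.n_lines):
        y_lo = plan.line_y(i) - 1.5 * plan.line_interval / 2.0
        ys = y_lo + (np.arange(w_px) + 0.5) * mm_per_pixel
        strip = np.empty((w_px, n_along, 3))
        strip[:] = _BACKGROUND_RGB
        if outlines:
            gx, gy = np.meshgrid(xs, ys)
            pts = shapely.points(np.stack([gx.ravel(), gy.ravel()], axis=1))
            for line, style in outlines:
                d = shapely.distance(pts, line)
                on = d <= half_w
                if style["dash"] is not None and on.any():
                    s = shapely.line_locate_point(line, pts[on])
                    period = style["dash"][0] + style["dash"][1]
                    visible = np.mod(s, period) < style["dash"][0]
                    idx = np.flatnonzero(on)
                    on = np.zeros_like(on)
                    on[idx[visible]] = True
                mask = on.reshape(w_px, n_along)
                strip[mask] = style["rgb"]
        strips.append(strip)
    return strips
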