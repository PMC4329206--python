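"""Raster scanning: magnetic image construction and the optical line mosaic.

A scan is a set of parallel lines along x at a fixed line interval in y.
Each magnetic pixel is the probe signal of one scanning step; every line
starts and ends in free space (>= 10 mm outside the scene support) and is
baseline-corrected against the free-space signal level at its ends.  The
optical image is a mosaic of per-line panorama strips, each cropped to its
central 2/3 across track, in the same millimetre frame as the magnetic
image.  In the noiseless model pixel values are independent of scan speed
(scanning and static acquisition coincide); speed only sets the per-pixel
dwell time and hence the noise bandwidth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .forward import DEFAULT_SCAN_MARGIN, ProbeConfig, Scene, probe_signal_map

__all__ = [
    "ScanPlan",
    "MagneticImage",
    "OpticalImage",
    "acquire_magnetic_image",
    "baseline_correct",
    "build_optical_image",
    "scan_duration",
]


@dataclass(frozen=True)
class ScanPlan:
    """A raster of scan lines along x, stacked in y.

    ``x_start``/``x_end`` are the first/last sampled probe positions on every
    line; ``y_start`` is the y of line 0 and lines advance by
    ``line_interval``.  ``free_space_margin`` is the minimum clearance each
    line end must keep outside the scene support.
    """

    x_start: float
    x_end: float
    y_start: float
    n_lines: int
    step: float = 5.0  # mm between samples along a line
    line_interval: float = 5.0  # mm between lines
    speed: float = 5.0  # mm/s along the line
    free_space_margin: float = 10.0  # mm

    def __post_init__(self) -> None:
        if self.step <= 0 or self.line_interval <= 0 or self.speed <= 0:
            raise ValueError("step, line_interval and speed must be > 0")
        if self.n_lines < 1:
            raise ValueError("need at least one scan line")
        if self.x_end <= self.x_start:
            raise ValueError("x_end must exceed x_start")
        if self.free_space_margin < 10.0:
            raise ValueError("free_space_margin must be >= 10 mm")

    @property
    def n_cols(self) -> int:
        return int(np.floor((self.x_end - self.x_start) / self.step + 1e-9)) + 1

    @property
    def line_length(self) -> float:
        return self.x_end - self.x_start

    @property
    def dwell_time(self) -> float:
        """Seconds spent traversing one step (= per-pixel averaging time)."""
        return self.step / self.speed

    def line_y(self, i: int) -> float:
        return self.y_start + i * self.line_interval

    @property
    def line_ys(self) -> np.ndarray:
        return self.y_start + np.arange(self.n_lines) * self.line_interval

    @property
    def xs(self) -> np.ndarray:
        return self.x_start + np.arange(self.n_cols) * self.step

    @classmethod
    def cover(
        cls,
        scene: Scene,
        step: float = 5.0,
        line_interval: float = 5.0,
        speed: float = 5.0,
        free_space_margin: float = DEFAULT_SCAN_MARGIN,
        margin_y: float = 30.0,
    ) -> "ScanPlan":
        """A plan whose lines cover the scene with free space at both ends.

        ``free_space_margin`` sets the along-line clearance needed for a
        clean baseline; ``margin_y`` only extends the across-track coverage
        so half-max masks close within the image at deep standoffs.
        """
        xmin, xmax, ymin, ymax = scene.support_bounds()
        x0 = step * np.floor((xmin - free_space_margin) / step)
        nx = int(np.ceil((xmax + free_space_margin - x0) / step))
        y0 = line_interval * np.floor((ymin - margin_y) / line_interval)
        n_lines = int(np.ceil((ymax + margin_y - y0) / line_interval)) + 1
        return cls(
            x_start=float(x0),
            x_end=float(x0 + nx * step),
            y_start=float(y0),
            n_lines=n_lines,
            step=step,
            line_interval=line_interval,
            speed=speed,
            free_space_margin=free_space_margin,
        )

    def validate_for(self, scene: Scene) -> None:
        """Check every line starts and ends in free space; raise otherwise."""
        if scene.n_voxels == 0 and not scene.ground_truth:
            return
        xmin, xmax, _, _ = scene.support_bounds()
        if self.x_start > xmin - self.free_space_margin + 1e-9:
            raise ValueError(
                "scan lines must start >= free_space_margin outside the scene "
                f"(x_start={self.x_start}, scene xmin={xmin})"
            )
        if self.x_end < xmax + self.free_space_margin - 1e-9:
            raise ValueError(
                "scan lines must end >= free_space_margin outside the scene "
                f"(x_end={self.x_end}, scene xmax={xmax})"
            )


@dataclass
class MagneticImage:
    """Grid of I values (Volt), one row per scan line.

    ``origin`` is the (x, y) mm position of the centre of pixel (row 0,
    col 0); x advances with columns, y with rows, both by ``pixel_spacing``.
    """

    data: np.ndarray
    pixel_spacing: float = 5.0
    origin: tuple[float, float] = (0.0, 0.0)
    baseline_corrected: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("image data must be 2-D (lines x samples)")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def pixel_center(self, row, col) -> tuple:
        """mm coordinates (x, y) of a pixel centre; accepts arrays."""
        x = self.origin[0] + np.asarray(col) * self.pixel_spacing
        y = self.origin[1] + np.asarray(row) * self.pixel_spacing
        return x, y

    @property
    def xs(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.data.shape[1]) * self.pixel_spacing

    @property
    def ys(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.data.shape[0]) * self.pixel_spacing

    def peak_position(self) -> tuple[float, float]:
        r, c = np.unravel_index(int(np.argmax(self.data)), self.data.shape)
        x, y = self.pixel_center(r, c)
        return float(x), float(y)

    def to_csv(self, path, sidecar: bool = True) -> None:
        np.savetxt(path, self.data, delimiter=",")
        if sidecar:
            meta = {
                "pixel_spacing": self.pixel_spacing,
                "origin": list(self.origin),
                "baseline_corrected": self.baseline_corrected,
                **self.metadata,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "MagneticImage":
        data = np.atleast_2d(np.loadtxt(path, delimiter=","))
        meta_path = str(path) + ".json"
        kwargs: dict = {}
        try:
            with open(meta_path) as fh:
                meta = json.load(fh)
            kwargs = {
                "pixel_spacing": meta.pop("pixel_spacing", 5.0),
                "origin": tuple(meta.pop("origin", (0.0, 0.0))),
                "baseline_corrected": meta.pop("baseline_corrected", False),
                "metadata": meta,
            }
        except FileNotFoundError:
            pass
        return cls(data, **kwargs)


@dataclass
class OpticalImage:
    """RGB mosaic in the scan frame; values in [0, 1], row = y, col = x."""

    data: np.ndarray
    mm_per_pixel: float
    origin: tuple[float, float] = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("optical data must be (H, W, 3)")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be > 0")

    @property
    def xs(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.data.shape[1]) * self.mm_per_pixel

    @property
    def ys(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.data.shape[0]) * self.mm_per_pixel

    def to_png(self, path) -> None:
        from PIL import Image

        arr = np.clip(self.data * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)

    @classmethod
    def from_png(cls, path, mm_per_pixel: float, origin=(0.0, 0.0)) -> "OpticalImage":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0
        return cls(arr, mm_per_pixel=mm_per_pixel, origin=origin)


def baseline_correct(raw: np.ndarray, mode: str = "ends_mean") -> np.ndarray:
    """Subtract each line's free-space baseline from the raw line signals.

    ``ends_mean`` (default): the mean of the first and last sample of the
    line.  ``linear``: a linear drift interpolated from the first to the last
    sample (for slow per-line drifts).
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[1] < 2:
        raise ValueError("need >= 2 samples per line to estimate a baseline")
    first = raw[:, :1]
    last = raw[:, -1:]
    if mode == "ends_mean":
        return raw - (first + last) / 2.0
    if mode == "linear":
        frac = np.linspace(0.0, 1.0, raw.shape[1])[None, :]
        return raw - (first + (last - first) * frac)
    raise ValueError(f"unknown baseline mode: {mode!r}")


def acquire_magnetic_image(
    scene: Scene,
    plan: ScanPlan,
    probe: ProbeConfig,
    rng: np.random.Generator | None = None,
    baseline_mode: str = "ends_mean",
) -> MagneticImage:
    """Simulate a full raster scan and return the baseline-corrected image.

    One probe signal per scanning step (dwell = step / speed); per line the
    free-space baseline is estimated from the line's end samples and
    subtracted.  Requires ``step == line_interval`` so the image has square
    pixels (both default to 5 mm).
    """
    if abs(plan.step - plan.line_interval) > 1e-12:
        raise ValueError("square pixels required: step must equal line_interval")
    plan.validate_for(scene)
    xs = plan.xs
    ys = plan.line_ys
    gx, gy = np.meshgrid(xs, ys)
    positions = np.stack([gx.ravel(), gy.ravel()], axis=1)
    raw = probe_signal_map(
        scene, positions, probe, rng=rng, dwell_time=plan.dwell_time
    ).reshape(plan.n_lines, plan.n_cols)
    corrected = baseline_correct(raw, mode=baseline_mode)
    return MagneticImage(
        corrected,
        pixel_spacing=plan.step,
        origin=(float(xs[0]), float(ys[0])),
        baseline_corrected=True,
        metadata={"baseline_mode": baseline_mode, "dwell_time_s": plan.dwell_time},
    )


def build_optical_image(
    line_panoramas: list[np.ndarray],
    plan: ScanPlan,
    mm_per_pixel: float = 0.5,
) -> OpticalImage:
    """Mosaic per-line panorama strips into one optical image.

    Each strip is an (across_track, along_track, 3) RGB array covering the
    full line; only the central 2/3 of the across-track extent is retained
    (the panorama edges are distorted), and retained bands are stacked in
    line order.  The retained band must tile the line interval exactly.
    """
    if not line_panoramas:
        raise ValueError("no line panoramas given")
    shapes = {s.shape for s in line_panoramas}
    if len(shapes) != 1:
        raise ValueError(f"panorama strips differ in shape: {shapes}")
    if len(line_panoramas) != plan.n_lines:
        raise ValueError("need exactly one panorama per scan line")
    w = line_panoramas[0].shape[0]
    retained = (2 * w) // 3
    start = (w - retained) // 2
    band_mm = retained * mm_per_pixel
    if abs(band_mm - plan.line_interval) > 1e-9:
        raise ValueError(
            f"retained band ({band_mm} mm) must equal the line interval "
            f"({plan.line_interval} mm); adjust strip width or mm_per_pixel"
        )
    bands = [np.asarray(s, dtype=float)[start : start + retained] for s in line_panoramas]
    mosaic = np.concatenate(bands, axis=0)
    # strip columns span [x_start - step/2, x_end + step/2]; rows of band i
    # span [line_y(i) - interval/2, line_y(i) + interval/2]
    x0 = plan.x_start - plan.step / 2.0 + mm_per_pixel / 2.0
    y0 = plan.line_y(0) - plan.line_interval / 2.0 + mm_per_pixel / 2.0
    return OpticalImage(mosaic, mm_per_pixel=mm_per_pixel, origin=(x0, y0))


def scan_duration(plan: ScanPlan) -> float:
    """Total in-line scan time in seconds (turnaround between lines excluded)."""
    return plan.n_lines * plan.line_length / plan.speed
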