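import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssbdual.forward import Scene
from ssbdual.imaging import (
    MagneticImage,
    ScanPlan,
    acquire_magnetic_image,
    baseline_correct,
    build_optical_image,
    scan_duration,
)
from ssbdual.synthetic import PhantomSpec, make_optical_panoramas, make_phantom_scene


def plan_for_tests(**kw):
    kw.setdefault("x_start", -50.0)
    kw.setdefault("x_end", 50.0)
    kw.setdefault("y_start", -10.0)
    kw.setdefault("n_lines", 5)
    return ScanPlan(**kw)


# --- plan geometry ---------------------------------------------------------


def test_pixel_count_per_line():
    assert plan_for_tests().n_cols == 21
    assert plan_for_tests(x_end=48.0).n_cols == 20  # floor(98/5)+1


def test_plan_validation():
    with pytest.raises(ValueError):
        plan_for_tests(step=0.0)
    with pytest.raises(ValueError):
        plan_for_tests(free_space_margin=5.0)  # below the 10 mm floor
    with pytest.raises(ValueError):
        plan_for_tests(x_end=-60.0)


def test_plan_rejects_scene_without_free_space():
    scene = make_phantom_scene(PhantomSpec())
    tight = plan_for_tests(x_start=-10.0, x_end=10.0)
    with pytest.raises(ValueError):
        tight.validate_for(scene)


def test_cover_leaves_free_space():
    scene = make_phantom_scene(PhantomSpec())
    plan = ScanPlan.cover(scene)
    plan.validate_for(scene)
    xmin, xmax, _, _ = scene.support_bounds()
    assert plan.x_start <= xmin - plan.free_space_margin
    assert plan.x_end >= xmax + plan.free_space_margin


# --- scan duration ---------------------------------------------------------


@pytest.mark.parametrize(
    "n_lines,length,speed,expected_s",
    [(1, 100.0, 5.0, 20.0), (2, 100.0, 5.0, 40.0), (10, 75.0, 5.0, 150.0)],
)
def test_scan_duration(n_lines, length, speed, expected_s):
    plan = plan_for_tests(x_start=0.0, x_end=length, n_lines=n_lines, speed=speed)
    assert scan_duration(plan) == pytest.approx(expected_s)


# --- baseline correction ---------------------------------------------------


@settings(derandomize=True, max_examples=30)
@given(offsets=st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=3, max_size=3))
def test_baseline_removes_any_per_line_offset(offsets):
    base = np.array([[0.0, 1.0, 3.0, 1.0, 0.0]] * 3)
    shifted = base + np.asarray(offsets)[:, None]
    assert baseline_correct(shifted) == pytest.approx(baseline_correct(base))


def test_baseline_modes():
    line = np.array([[1.0, 2.0, 5.0, 2.0, 3.0]])
    ends_mean = baseline_correct(line)
    assert ends_mean[0, 0] == pytest.approx(-1.0)  # 1 - (1+3)/2
    assert ends_mean[0, -1] == pytest.approx(1.0)
    linear = baseline_correct(line, mode="linear")
    assert linear[0, 0] == 0.0 and linear[0, -1] == 0.0
    with pytest.raises(ValueError):
        baseline_correct(line, mode="nope")
    with pytest.raises(ValueError):
        baseline_correct(np.ones((2, 1)))


# --- magnetic acquisition --------------------------------------------------


def test_empty_scene_noiseless_image_is_zero(probe):
    scene = Scene(np.empty((0, 3)), np.empty((0,)))
    img = acquire_magnetic_image(scene, plan_for_tests(), probe)
    assert np.all(img.data == 0.0)
    assert img.baseline_corrected
    assert img.shape == (5, 21)


def test_acquire_requires_square_pixels(probe):
    scene = Scene(np.empty((0, 3)), np.empty((0,)))
    with pytest.raises(ValueError):
        acquire_magnetic_image(scene, plan_for_tests(line_interval=4.0), probe)


def test_pixel_values_independent_of_speed(probe, phantom_scan):
    """Noiseless scanning equals a static acquisition at any speed."""
    scene, plan, img, _ = phantom_scan
    import dataclasses

    fast = dataclasses.replace(plan, speed=50.0)
    img_fast = acquire_magnetic_image(scene, fast, probe)
    assert img_fast.data == pytest.approx(img.data, rel=1e-12)


def test_peak_and_optical_marker_share_frame(probe, phantom_scan):
    """A point-like source's image peak sits within one pixel of its marker."""
    scene, plan, img, _ = phantom_scan
    px, py = img.peak_position()
    assert abs(px - 0.0) <= img.pixel_spacing
    assert abs(py - 0.0) <= img.pixel_spacing


def test_image_round_trip_csv(tmp_path, phantom_scan):
    _, _, img, _ = phantom_scan
    path = tmp_path / "img.csv"
    img.to_csv(path)
    back = MagneticImage.from_csv(path)
    assert back.data == pytest.approx(img.data)
    assert back.pixel_spacing == img.pixel_spacing
    assert back.origin == img.origin
    assert back.baseline_corrected


def test_image_validation():
    with pytest.raises(ValueError):
        MagneticImage(np.array([[np.inf, 0.0]]))
    with pytest.raises(ValueError):
        MagneticImage(np.zeros((2, 2)), pixel_spacing=0.0)


# --- optical mosaic --------------------------------------------------------


def test_central_two_thirds_crop_width():
    plan = plan_for_tests(n_lines=2)
    strips = [np.ones((30, 40, 3)) for _ in range(2)]
    opt = build_optical_image(strips, plan, mm_per_pixel=0.25)
    assert opt.data.shape == (40, 40, 3)  # 2 lines x 20 retained rows


def test_uniform_strips_give_uniform_image():
    plan = plan_for_tests(n_lines=3)
    strips = [np.full((15, 30, 3), 0.5) for _ in range(3)]
    opt = build_optical_image(strips, plan, mm_per_pixel=0.5)
    assert np.all(opt.data == 0.5)


def test_mismatched_strips_rejected():
    plan = plan_for_tests(n_lines=2)
    strips = [np.ones((15, 30, 3)), np.ones((15, 31, 3))]
    with pytest.raises(ValueError):
        build_optical_image(strips, plan, mm_per_pixel=0.5)
    with pytest.raises(ValueError):
        build_optical_image([np.ones((15, 30, 3))] * 2, plan, mm_per_pixel=0.4)


def test_ground_truth_disk_round_trips_through_mosaic():
    """A circle drawn in the panoramas reappears at its mm position."""
    spec = PhantomSpec(center_xy=(5.0, -5.0))
    scene = make_phantom_scene(spec)
    plan = ScanPlan.cover(scene)
    strips = make_optical_panoramas(scene, plan)
    opt = build_optical_image(strips, plan)
    brown = (
        (np.abs(opt.data[..., 0] - 0.55) < 0.05)
        & (np.abs(opt.data[..., 2] - 0.12) < 0.05)
    )
    assert brown.sum() > 10
    ys, xs = np.nonzero(brown)
    cx, cy = opt.xs[xs].mean(), opt.ys[ys].mean()
    assert cx == pytest.approx(5.0, abs=opt.mm_per_pixel)
    assert cy == pytest.approx(-5.0, abs=opt.mm_per_pixel)


def test_optical_png_round_trip(tmp_path):
    plan = plan_for_tests(n_lines=2)
    strips = [np.full((15, 30, 3), 0.25) for _ in range(2)]
    opt = build_optical_image(strips, plan, mm_per_pixel=0.5)
    path = tmp_path / "opt.png"
    opt.to_png(path)
    from ssbdual.imaging import OpticalImage

    back = OpticalImage.from_png(path, mm_per_pixel=0.5, origin=opt.origin)
    assert back.data == pytest.approx(opt.data, abs=1 / 255)
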