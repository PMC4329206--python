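import numpy as np
import pytest

from conftest import toy_image
from ssbdual.spots import (
    DetectionConfig,
    detect_spots,
    estimate_noise_sigma,
    filter_spot_half_max,
    half_max_contour,
    image_summary,
    integral_of_I,
)

DET0 = DetectionConfig(noise_sigma_estimate=0.0)


def test_all_zero_image_has_no_spots():
    img = toy_image(np.zeros((4, 6)))
    assert detect_spots(img, DET0) == []
    summary = image_summary(img, DET0)
    assert summary["I_max_global"] == 0.0
    assert summary["total_integral"] == 0.0


def test_single_suprathreshold_pixel_is_one_spot():
    data = np.zeros((4, 6))
    data[2, 3] = 0.7
    spots = detect_spots(toy_image(data), DET0)
    assert len(spots) == 1
    assert spots[0].pixels == {(2, 3)}
    assert spots[0].I_max == pytest.approx(0.7)
    assert spots[0].filtered_pixels == {(2, 3)}  # 1-px spot keeps its peak


def test_two_blobs_with_subthreshold_gap_are_two_spots():
    """Hand-enumerated 5x7 case: a zero column separates two 8-connected blobs."""
    data = np.zeros((5, 7))
    data[1:3, 1:3] = [[1.0, 0.8], [0.6, 0.9]]
    data[2:4, 4:6] = [[0.5, 0.4], [0.45, 0.2]]
    spots = detect_spots(toy_image(data), DET0)
    assert len(spots) == 2
    assert spots[0].I_max == pytest.approx(1.0)  # sorted brightest first
    assert spots[0].pixels == {(1, 1), (1, 2), (2, 1), (2, 2)}
    assert spots[1].pixels == {(2, 4), (2, 5), (3, 4), (3, 5)}


def test_diagonal_pixels_merge_under_8_but_not_4_connectivity():
    data = np.zeros((3, 3))
    data[0, 0] = 1.0
    data[1, 1] = 0.9
    img = toy_image(data)
    assert len(detect_spots(img, DET0)) == 1
    det4 = DetectionConfig(noise_sigma_estimate=0.0, connectivity=4)
    assert len(detect_spots(img, det4)) == 2


def test_half_max_filter_hand_case():
    """Values {1.0, 0.6, 0.2}: the 50% rule keeps {1.0, 0.6} only."""
    data = np.zeros((3, 5))
    data[1, 1:4] = [1.0, 0.6, 0.2]
    img = toy_image(data)
    (spot,) = detect_spots(img, DET0)
    mask = filter_spot_half_max(spot, img)
    assert sorted(spot.values[mask].tolist()) == [0.6, 1.0]
    assert integral_of_I(spot, 5.0) == pytest.approx(40.0)  # 1.6 * 25 mm^2
    assert integral_of_I(spot, 5.0, mode="spacing") == pytest.approx(8.0)


def test_uniform_spot_keeps_all_pixels():
    data = np.zeros((4, 4))
    data[1:3, 1:3] = 0.3
    (spot,) = detect_spots(toy_image(data), DET0)
    assert spot.n_filtered == 4
    assert spot.integral_I == pytest.approx(4 * 0.3 * 25)


def test_per_spot_threshold_locality():
    """Scaling one component never changes another component's mask/integral."""
    data = np.zeros((5, 9))
    data[1:3, 1:3] = [[1.0, 0.6], [0.2, 0.4]]
    data[1:3, 6:8] = [[0.08, 0.05], [0.02, 0.06]]
    img = toy_image(data)
    spots = {tuple(sorted(s.pixels))[0][1] < 5: s for s in detect_spots(img, DET0)}
    left, right = spots[True], spots[False]

    data10 = data.copy()
    data10[1:3, 1:3] *= 10.0
    spots10 = {tuple(sorted(s.pixels))[0][1] < 5: s for s in
               detect_spots(toy_image(data10), DET0)}
    assert spots10[False].filtered_pixels == right.filtered_pixels
    assert spots10[False].integral_I == pytest.approx(right.integral_I)
    assert spots10[True].integral_I == pytest.approx(10 * left.integral_I)


def test_integral_scales_linearly_with_image():
    data = np.zeros((4, 6))
    data[1:3, 1:4] = [[0.9, 0.5, 0.1], [0.3, 0.44, 0.2]]
    img = toy_image(data)
    (s1,) = detect_spots(img, DET0)
    (s2,) = detect_spots(toy_image(3.0 * data), DET0)
    assert s2.integral_I == pytest.approx(3.0 * s1.integral_I)
    assert s2.filtered_pixels == s1.filtered_pixels


def test_summary_of_two_disjoint_spots_sums():
    data = np.zeros((5, 9))
    data[1, 1] = 1.0
    data[3, 7] = 0.4
    summary = image_summary(toy_image(data), DET0)
    assert summary["I_max_global"] == pytest.approx(1.0)
    assert summary["total_integral"] == pytest.approx((1.0 + 0.4) * 25)
    assert len(summary["table"]) == 2


def test_plain_sum_mode():
    data = np.zeros((3, 5))
    data[1, 1:4] = [1.0, 0.6, 0.2]
    det = DetectionConfig(noise_sigma_estimate=0.0, sum_mode="plain_sum")
    assert image_summary(toy_image(data), det)["total_integral"] == pytest.approx(1.6)


def test_noise_estimate_from_line_ends():
    rng = np.random.default_rng(0)
    sigma = 0.05
    raw = rng.normal(0, sigma, size=(200, 30))
    from ssbdual.imaging import baseline_correct

    img = toy_image(baseline_correct(raw))
    assert estimate_noise_sigma(img) == pytest.approx(sigma, rel=0.15)
    with pytest.raises(ValueError):
        estimate_noise_sigma(toy_image(np.zeros((3, 1))))


def test_detection_level_uses_k_sigma():
    data = np.zeros((3, 5))
    data[1, 2] = 0.9
    data[1, 0] = 0.25  # below 3*sigma for sigma=0.1
    det = DetectionConfig(noise_sigma_estimate=0.1)
    spots = detect_spots(toy_image(data), det)
    assert len(spots) == 1 and spots[0].pixels == {(1, 2)}


def test_half_max_contour_encircles_symmetric_peak():
    """Contour of a discretised radial peak closes around the peak centre."""
    xs = np.arange(-30, 31, 5.0)
    gx, gy = np.meshgrid(xs, xs)
    data = np.exp(-(gx**2 + gy**2) / (2 * 12.0**2))
    img = toy_image(data, origin=(-30.0, -30.0))
    (spot,) = detect_spots(img, DetectionConfig(noise_sigma_estimate=1e-3))
    poly = half_max_contour(spot, img)
    assert np.allclose(poly[0], poly[-1])
    cx, cy = poly[:-1, 0].mean(), poly[:-1, 1].mean()
    assert abs(cx) < 0.5 and abs(cy) < 0.5
    # FWHM radius of the Gaussian is sigma*sqrt(2 ln 2) ~ 14.1 mm
    r = np.hypot(poly[:, 0] - cx, poly[:, 1] - cy)
    assert r.mean() == pytest.approx(12.0 * np.sqrt(2 * np.log(2)), rel=0.15)


def test_half_max_contour_scale_invariant():
    xs = np.arange(-30, 31, 5.0)
    gx, gy = np.meshgrid(xs, xs)
    data = np.exp(-(gx**2 + gy**2) / (2 * 10.0**2))
    det = DetectionConfig(noise_sigma_estimate=1e-3)
    img1 = toy_image(data, origin=(-30.0, -30.0))
    img2 = toy_image(7.0 * data, origin=(-30.0, -30.0))
    p1 = half_max_contour(detect_spots(img1, det)[0], img1)
    p2 = half_max_contour(detect_spots(img2, det)[0], img2)
    assert p1 == pytest.approx(p2)


def test_half_max_contour_degenerate_spot_warns():
    data = np.zeros((4, 6))
    data[1, 2] = 1.0
    data[1, 3] = 0.9
    img = toy_image(data)
    (spot,) = detect_spots(img, DET0)
    with pytest.warns(RuntimeWarning):
        poly = half_max_contour(spot, img)
    assert poly.shape[1] == 2 and np.allclose(poly[0], poly[-1])


def test_config_validation():
    with pytest.raises(ValueError):
        DetectionConfig(k_sigma=0.0)
    with pytest.raises(ValueError):
        DetectionConfig(connectivity=6)
    with pytest.raises(ValueError):
        DetectionConfig(integral_mode="volume")
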