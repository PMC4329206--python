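import numpy as np
import pytest

from ssbdual.forward import (
    EMU_TO_AM2,
    MU0_OVER_4PI,
    ProbeConfig,
    Scene,
    SourceVoxel,
    cylinder_voxels,
    excitation_field,
    gradiometer_signal,
    induced_moment,
    noise_sigma,
    probe_signal,
    probe_signal_map,
)


# --- excitation coil -------------------------------------------------------


def test_excitation_center_field(probe):
    assert excitation_field(probe, (0, 0, 0)) == pytest.approx(120.0)


def test_excitation_on_axis_one_radius(probe):
    a = probe.excitation_radius
    assert excitation_field(probe, (0, 0, -a)) == pytest.approx(120 / 2**1.5)


def test_excitation_far_field_slope(probe):
    """log-log slope of on-axis field vs distance tends to -3 (dipole limit)."""
    z = np.array([500.0, 1000.0])
    h = np.array([excitation_field(probe, (0, 0, -zi)) for zi in z])
    slope = np.log(h[1] / h[0]) / np.log(z[1] / z[0])
    assert slope == pytest.approx(-3.0, abs=0.01)


def test_excitation_matches_biot_savart_line_integral(probe):
    """Off-axis elliptic form agrees with direct segment-wise Biot-Savart."""
    a = probe.excitation_radius
    phi = np.linspace(0, 2 * np.pi, 20001)[:-1]
    dphi = phi[1] - phi[0]
    wire = np.stack([a * np.cos(phi), a * np.sin(phi), np.zeros_like(phi)], axis=1)
    dl = np.stack(
        [-a * np.sin(phi) * dphi, a * np.cos(phi) * dphi, np.zeros_like(phi)], axis=1
    )

    def numeric(point):
        r = np.asarray(point) - wire
        rn = np.linalg.norm(r, axis=1, keepdims=True)
        db = np.cross(dl, r) / rn**3
        return db.sum(axis=0)

    b0 = np.linalg.norm(numeric((0.0, 0.0, 0.0)))
    rng = np.random.default_rng(3)
    for _ in range(5):
        pt = rng.uniform([-20, -20, -60], [20, 20, -10])
        expected = 120.0 * np.linalg.norm(numeric(pt)) / b0
        assert excitation_field(probe, pt) == pytest.approx(expected, rel=1e-5)


def test_excitation_singular_on_wire(probe):
    with pytest.raises(ValueError):
        excitation_field(probe, (probe.excitation_radius, 0.0, 0.0))


# --- induced moment --------------------------------------------------------


def test_induced_moment_linear_response():
    assert induced_moment(0.075, 120.0) == pytest.approx(0.075)
    assert induced_moment(0.075, 0.0) == 0.0
    assert induced_moment(0.075, 60.0) == pytest.approx(
        0.5 * induced_moment(0.075, 120.0)
    )
    with pytest.raises(ValueError):
        induced_moment(0.075, -1.0)


# --- gradiometer flux quadrature ------------------------------------------


def _brute_force_gradiometer(probe, moment, pos, n=400):
    """Midpoint polar-grid quadrature at ~10x the adaptive base resolution."""
    area = np.pi * (probe.pickup_radius * 1e-3) ** 2

    def flux(zl):
        edges = np.linspace(0, probe.pickup_radius, n + 1)
        rc = 0.5 * (edges[1:] + edges[:-1])
        nphi = 4 * n
        phi = (np.arange(nphi) + 0.5) * 2 * np.pi / nphi
        w = np.repeat(rc * np.diff(edges), nphi) * (2 * np.pi / nphi)
        x = np.outer(rc, np.cos(phi)).ravel()
        y = np.outer(rc, np.sin(phi)).ravel()
        s = 1e-3
        dx, dy, dz = x - pos[0], y - pos[1], zl - pos[2]
        r2 = (dx**2 + dy**2 + dz**2) * s * s
        bz = MU0_OVER_4PI * moment * EMU_TO_AM2 * (3 * (dz * s) ** 2 - r2) / r2**2.5
        return float((bz * w * s * s).sum())

    return (flux(probe.lower_loop_z) - flux(probe.upper_loop_z)) / area


def test_gradiometer_quadrature_matches_brute_force(probe):
    """Adaptive flux quadrature within 1% of a much finer brute-force grid."""
    rng = np.random.default_rng(11)
    for _ in range(5):
        pos = rng.uniform([-40, -40, -70], [40, 40, -20])
        g = gradiometer_signal(probe, 1e-3, pos)
        b = _brute_force_gradiometer(probe, 1e-3, pos)
        assert g == pytest.approx(b, rel=0.01)


def test_gradiometer_zero_moment_and_additivity(probe):
    pos = (3.0, -4.0, -40.0)
    assert gradiometer_signal(probe, 0.0, pos) == 0.0
    s1 = gradiometer_signal(probe, 2e-4, pos)
    s2 = gradiometer_signal(probe, 5e-4, pos)
    s12 = gradiometer_signal(probe, 7e-4, pos)
    assert s12 == pytest.approx(s1 + s2, rel=1e-9)


def test_gradiometer_rejects_source_above_lower_loop(probe):
    with pytest.raises(ValueError):
        gradiometer_signal(probe, 1e-3, (0, 0, probe.lower_loop_z + 1))


def test_gradiometer_reciprocity_cross_check(probe):
    """Flux from reciprocity (loop field at the dipole) agrees with quadrature.

    By reciprocity the flux a dipole m sends through a loop equals m dotted
    with the loop's field per unit current at the dipole position - an
    independent closed-form (elliptic integral) route to the same quantity.
    """
    from scipy.special import ellipe, ellipk

    def loop_bz_unit_current(R_mm, zl_mm, pos_mm):
        rho = np.hypot(pos_mm[0], pos_mm[1]) * 1e-3
        z = (pos_mm[2] - zl_mm) * 1e-3
        R = R_mm * 1e-3
        q2 = (R + rho) ** 2 + z**2
        m = 4 * R * rho / q2
        pref = 2 * MU0_OVER_4PI / np.sqrt(q2)
        return pref * (
            ellipk(m) + ellipe(m) * (R**2 - rho**2 - z**2) / ((R - rho) ** 2 + z**2)
        )

    area = np.pi * (probe.pickup_radius * 1e-3) ** 2
    rng = np.random.default_rng(5)
    for _ in range(3):
        pos = rng.uniform([-30, -30, -60], [30, 30, -15])
        m_si = 1e-3 * EMU_TO_AM2
        expected = (
            m_si
            * (
                loop_bz_unit_current(probe.pickup_radius, probe.lower_loop_z, pos)
                - loop_bz_unit_current(probe.pickup_radius, probe.upper_loop_z, pos)
            )
            / area
        )
        assert gradiometer_signal(probe, 1e-3, pos) == pytest.approx(expected, rel=1e-4)


# --- full signal chain -----------------------------------------------------


def test_empty_scene_gives_zero_signal(probe):
    scene = Scene(np.empty((0, 3)), np.empty((0,)))
    assert probe_signal(scene, (0.0, 0.0), probe) == 0.0


def test_signal_linear_in_magnetism(probe):
    pos = np.array([[2.0, 1.0, -35.0], [-3.0, 0.0, -40.0]])
    mag = np.array([1e-3, 2e-3])
    s1 = probe_signal(Scene(pos, mag), (0, 0), probe)
    s3 = probe_signal(Scene(pos, 3 * mag), (0, 0), probe)
    assert s3 == pytest.approx(3 * s1, rel=1e-12)


def test_superposition_of_voxels(probe):
    rng = np.random.default_rng(2)
    pos = rng.uniform([-20, -20, -60], [20, 20, -25], size=(6, 3))
    mag = rng.uniform(1e-4, 1e-3, size=6)
    total = probe_signal(Scene(pos, mag), (1.0, -2.0), probe)
    parts = sum(
        probe_signal(Scene(pos[i : i + 1], mag[i : i + 1]), (1.0, -2.0), probe)
        for i in range(6)
    )
    assert total == pytest.approx(parts, rel=1e-10)


def test_signal_strictly_decreasing_and_convex_in_depth(probe):
    """Noiseless point-source signal vs depth: monotone decreasing, convex."""
    depths = np.arange(31.0, 66.5, 1.0)
    vals = np.array(
        [
            probe_signal(Scene([[0, 0, -d]], [1e-3]), (0, 0), probe)
            for d in depths
        ]
    )
    d1 = np.diff(vals)
    assert np.all(d1 < 0)
    assert np.all(np.diff(d1) > 0)


def test_lateral_response_symmetric(probe):
    scene = Scene([[0.0, 0.0, -40.0]], [1e-3])
    offs = np.array([5.0, 12.5, 30.0])
    left = probe_signal_map(scene, np.stack([-offs, np.zeros(3)], axis=1), probe)
    right = probe_signal_map(scene, np.stack([offs, np.zeros(3)], axis=1), probe)
    up = probe_signal_map(scene, np.stack([np.zeros(3), offs], axis=1), probe)
    assert left == pytest.approx(right, rel=1e-10)
    assert up == pytest.approx(right, rel=1e-10)


def test_voxels_above_probe_plane_rejected(probe):
    scene = Scene([[0.0, 0.0, 1.0]], [1e-3])
    with pytest.raises(ValueError):
        probe_signal(scene, (0, 0), probe)


# --- noise model -----------------------------------------------------------


def test_noise_sigma_zero_density(probe):
    import dataclasses

    quiet = dataclasses.replace(probe, noise_density=0.0)
    assert noise_sigma(quiet, 1.0) == 0.0


def test_noise_sigma_dwell_scaling(probe):
    assert noise_sigma(probe, 4.0) == pytest.approx(0.5 * noise_sigma(probe, 1.0))
    with pytest.raises(ValueError):
        noise_sigma(probe, 0.0)


def test_noise_draws_match_sigma(probe):
    """Empirical sd of seeded signal noise within 3% of the analytic sigma."""
    rng = np.random.default_rng(123)
    scene = Scene(np.empty((0, 3)), np.empty((0,)))
    draws = probe_signal_map(scene, np.zeros((10_000, 2)), probe, rng=rng)
    assert np.std(draws) == pytest.approx(noise_sigma(probe, 1.0), rel=0.03)


# --- geometry helpers ------------------------------------------------------


def test_cylinder_voxel_count_matches_volume():
    """Voxel count approximates volume/voxel^3 to within one voxel layer."""
    d, vol, vox = 6.0, 250.0, 1.0
    pos = cylinder_voxels(d, vol, vox, top_z=-31.0)
    layer = np.pi * (d / 2 + vox) ** 2 / vox**2
    assert abs(len(pos) - vol / vox**3) <= layer
    assert pos[:, 2].max() <= -31.0
    r = np.hypot(pos[:, 0], pos[:, 1])
    assert r.max() <= d / 2


def test_source_voxel_validation():
    with pytest.raises(ValueError):
        SourceVoxel((0, 0, -30), -1e-3)
    with pytest.raises(ValueError):
        Scene([[0, 0, -30]], [-1.0])


def test_default_display_calibration(probe, phantom_scan):
    """The reference phantom's image peaks at 1.0 Volt by construction."""
    _, _, img, _ = phantom_scan
    assert img.data.max() == pytest.approx(1.0, rel=1e-9)


def test_far_field_excitation_scaling(probe):
    """H * z^3 constant within 2% beyond ten coil radii (far-field argument)."""
    a = probe.excitation_radius
    z = np.linspace(10 * a, 40 * a, 7)
    prod = np.array([excitation_field(probe, (0, 0, -zi)) * zi**3 for zi in z])
    assert prod.max() / prod.min() - 1 < 0.02
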