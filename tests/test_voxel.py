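"""Voxel dosimetry: phantoms, PSF blur, RC/phi, dose engines, DVH."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from y90dose.constants import Y90
from y90dose.voxel import (
    VoxelGrid,
    absorbed_fraction_sphere,
    compute_dvh,
    dose_map_kernel_convolution,
    dose_map_local_energy_deposition,
    gaussian_psf_blur,
    make_sphere_phantom,
    recovery_coefficient,
    voxel_energy_kernel,
)


def _activity_grid(values, spacing=1.0):
    return VoxelGrid(values=values, spacing_mm=(spacing,) * 3,
                     semantics="activity_bq")


# ---------------------------------------------------------------------------
# phantoms and PSF blur
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("d,vox", [(10.0, 0.5), (30.0, 1.0), (200.0, 1.0)])
def test_sphere_phantom_volume_within_one_percent(d, vox):
    ph = make_sphere_phantom(d, vox, padding_mm=2.0)
    analytic = np.pi / 6.0 * d**3
    assert ph.volume_mm3 == pytest.approx(analytic, rel=0.01)


def test_sphere_phantom_preconditions():
    with pytest.raises(ValueError):
        make_sphere_phantom(10.0, 3.0)  # voxel > d/4
    with pytest.raises(ValueError):
        make_sphere_phantom(-5.0, 0.5)


def test_blur_identity_at_zero_fwhm():
    ph = make_sphere_phantom(10.0, 1.0, padding_mm=5.0)
    out = gaussian_psf_blur(ph.grid, 0.0)
    assert np.array_equal(out.values, ph.grid.values)


def test_blur_conserves_counts_and_keeps_uniform_interior():
    ph = make_sphere_phantom(30.0, 1.0, padding_mm=21.0)
    out = gaussian_psf_blur(ph.grid, 5.0)
    assert out.values.sum() == pytest.approx(ph.grid.values.sum(), rel=1e-6)
    centre = tuple(s // 2 for s in out.values.shape)
    assert out.values[centre] == pytest.approx(1.0, abs=1e-6)


def test_blur_rejects_anisotropic_grids():
    grid = VoxelGrid(values=np.zeros((8, 8, 8)), spacing_mm=(1.0, 1.0, 2.0))
    with pytest.raises(ValueError, match="isotropic"):
        gaussian_psf_blur(grid, 3.0)


def test_large_sphere_edge_loss_matches_planar_oracle():
    """Counts kept in a d=200 sphere after a 7 mm blur: the planar edge-loss
    approximation sigma/sqrt(2*pi) * A/V predicts ~0.965."""
    rc = recovery_coefficient(200.0, 7.0, 1.0)
    sigma = 7.0 / 2.3548
    planar = 1.0 - sigma / np.sqrt(2 * np.pi) * 3.0 / 100.0
    assert rc == pytest.approx(planar, abs=0.005)


def test_recovery_coefficient_limits_and_value():
    assert recovery_coefficient(20.0, 0.0, 0.5) == pytest.approx(1.0)
    # analytic continuum oracle (Gaussian radial distribution vs sphere
    # chord overlap) gives RC(20, 5) = 0.750
    assert recovery_coefficient(20.0, 5.0, 0.5) == pytest.approx(0.750, abs=0.005)
    # strictly decreasing in FWHM at fixed diameter
    rcs = [recovery_coefficient(20.0, f, 1.0) for f in (1.0, 3.0, 5.0, 7.0)]
    assert np.all(np.diff(rcs) < 0)


# ---------------------------------------------------------------------------
# absorbed fractions and the voxel energy kernel
# ---------------------------------------------------------------------------

def test_voxel_kernel_sums_to_energy_per_decay(tissue_kernel):
    k = voxel_energy_kernel(tissue_kernel, 1.0)
    assert k.sum() == pytest.approx(tissue_kernel.total_energy_j(), rel=1e-12)
    assert k.min() >= 0


def test_point_source_profile_matches_radial_kernel(tissue_kernel):
    """Shell-averaged dose around a single-voxel source reproduces the
    radial kernel within 5% for 1-8 mm."""
    vox = 0.5
    n = 49
    act = np.zeros((n, n, n))
    act[n // 2, n // 2, n // 2] = 1.0  # 1 Bq
    dose = dose_map_kernel_convolution(_activity_grid(act, vox), tissue_kernel)
    c = (np.arange(n) - n // 2) * vox
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    decays = 1.0 / Y90.lambda_per_s
    for r0 in (1.0, 2.0, 4.0, 6.0, 8.0):
        shell = (r > r0 - 0.25) & (r <= r0 + 0.25)
        measured = dose.values[shell].mean() / decays
        expected = tissue_kernel.dose_at(r[shell]).mean()
        assert measured == pytest.approx(expected, rel=0.05)


def test_uniform_activity_centre_matches_local_deposition(tissue_kernel):
    """In a large uniform volume the convolution dose converges to the LED
    dose (phi -> 1)."""
    n = 41
    act = np.full((n, n, n), 1e4)
    grid = _activity_grid(act, 1.0)
    conv = dose_map_kernel_convolution(grid, tissue_kernel)
    led = dose_map_local_energy_deposition(grid, density_g_cm3=1.04)
    centre = (n // 2,) * 3
    assert conv.values[centre] == pytest.approx(led.values[centre], rel=0.02)


def test_convolution_linearity_for_disjoint_sources(tissue_kernel):
    n = 61
    a1 = np.zeros((n, n, n))
    a2 = np.zeros((n, n, n))
    a1[10, 10, 10] = 5e3
    a2[50, 48, 52] = 8e3
    d1 = dose_map_kernel_convolution(_activity_grid(a1), tissue_kernel).values
    d2 = dose_map_kernel_convolution(_activity_grid(a2), tissue_kernel).values
    d12 = dose_map_kernel_convolution(_activity_grid(a1 + a2), tissue_kernel).values
    np.testing.assert_allclose(d12, d1 + d2, rtol=1e-9, atol=1e-12)


def test_convolution_equals_brute_force_on_tiny_grid(tissue_kernel):
    """On a 3^3 grid the FFT convolution must equal explicit pairwise
    source-target summation with the same voxel kernel."""
    rng = np.random.default_rng(3)
    act = rng.random((3, 3, 3)) * 1e3
    grid = _activity_grid(act, 1.0)
    dose = dose_map_kernel_convolution(grid, tissue_kernel).values
    k = voxel_energy_kernel(tissue_kernel, 1.0)
    half = k.shape[0] // 2
    mass = grid.voxel_volume_cm3 * tissue_kernel.density_g_cm3 * 1e-3
    brute = np.zeros_like(act)
    for sx in range(3):
        for sy in range(3):
            for sz in range(3):
                decays = act[sx, sy, sz] / Y90.lambda_per_s
                for tx in range(3):
                    for ty in range(3):
                        for tz in range(3):
                            brute[tx, ty, tz] += (
                                decays
                                * k[half + tx - sx, half + ty - sy, half + tz - sz]
                                / mass
                            )
    np.testing.assert_allclose(dose, brute, rtol=1e-9)


def test_global_energy_conservation(tissue_kernel, rng):
    """Total deposited energy equals cumulated decays times energy per decay
    when the grid padding contains the full beta range."""
    act = np.zeros((41, 41, 41))
    act[14:27, 14:27, 14:27] = rng.random((13, 13, 13)) * 1e4
    grid = _activity_grid(act, 1.0)
    dose = dose_map_kernel_convolution(grid, tissue_kernel)
    voxel_mass_kg = grid.voxel_volume_cm3 * 1.04 * 1e-3
    deposited = dose.values.sum() * voxel_mass_kg
    emitted = act.sum() / Y90.lambda_per_s * tissue_kernel.total_energy_j()
    assert deposited == pytest.approx(emitted, rel=0.02)


def test_led_dose_value_and_equivalence():
    act = np.full((4, 4, 4), 1e6 * 1.25e-4)  # 1e6 Bq/cm3 at 0.5 mm voxels
    grid = VoxelGrid(values=act, spacing_mm=(0.5,) * 3, semantics="activity_bq")
    dose = dose_map_local_energy_deposition(grid, density_g_cm3=1.04)
    assert dose.values[0, 0, 0] == pytest.approx(48.0769, rel=1e-4)
    zero = dose_map_local_energy_deposition(
        VoxelGrid(values=np.zeros((3, 3, 3)), spacing_mm=(1.0,) * 3,
                  semantics="activity_bq")
    )
    assert np.all(zero.values == 0)


def test_absorbed_fraction_monotone_and_large_sphere_limit(tissue_kernel):
    phis = [absorbed_fraction_sphere(d, tissue_kernel, 1.0) for d in (10, 30, 60)]
    assert np.all(np.diff(phis) > 0)
    assert 0 < phis[0] < phis[-1] <= 1
    phi200 = absorbed_fraction_sphere(200.0, tissue_kernel, 1.0)
    assert phi200 == pytest.approx(0.98, abs=0.01)


def test_absorbed_fraction_grid_convergence(tissue_kernel):
    phi_coarse = absorbed_fraction_sphere(20.0, tissue_kernel, 1.0)
    phi_fine = absorbed_fraction_sphere(20.0, tissue_kernel, 0.5)
    assert abs(phi_fine - phi_coarse) < 0.005


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

def _dose_grid(values):
    return VoxelGrid(values=values, spacing_mm=(1.0,) * 3, semantics="dose_gy")


def test_dvh_uniform_dose_is_rectangular():
    dose = _dose_grid(np.full((5, 5, 5), 100.0))
    h = compute_dvh(dose, np.ones((5, 5, 5)))
    assert h.d_x(50.0) == pytest.approx(100.0)
    assert h.v_y(50.0) == pytest.approx(100.0)
    assert h.v_y(100.0) == pytest.approx(100.0)
    assert h.v_y(100.1) == pytest.approx(0.0)
    assert h.cumulative_fraction[0] == pytest.approx(1.0)


def test_dvh_two_level_distribution():
    values = np.concatenate([np.full(50, 10.0), np.full(50, 100.0)])
    dose = _dose_grid(values.reshape(2, 5, 10))
    h = compute_dvh(dose, np.ones((2, 5, 10)))
    assert h.v_y(10.0) == pytest.approx(100.0)
    assert h.v_y(100.0) == pytest.approx(50.0)
    assert h.d_x(50.0) == pytest.approx(100.0)  # ties toward the higher dose
    assert h.d_x(100.0) == pytest.approx(10.0)  # minimum dose
    assert h.d_x(0.1) == pytest.approx(100.0)  # -> maximum dose


def test_dvh_rejects_empty_mask():
    dose = _dose_grid(np.ones((3, 3, 3)))
    with pytest.raises(ValueError, match="empty"):
        compute_dvh(dose, np.zeros((3, 3, 3)))


@given(st.integers(0, 2**32 - 1))
def test_dvh_monotone_and_mean_identity(seed):
    rng = np.random.default_rng(seed)
    values = rng.gamma(2.0, 30.0, size=(6, 6, 6))
    mask = rng.random((6, 6, 6)) > 0.3
    if not mask.any():
        mask[0, 0, 0] = True
    h = compute_dvh(_dose_grid(values), mask.astype(float), bin_width_gy=1.0)
    assert np.all(np.diff(h.cumulative_fraction) <= 1e-12)
    assert h.mean_dose_gy == pytest.approx(values[mask].mean(), rel=1e-6)
    assert h.differential_cm3.sum() == pytest.approx(h.total_volume_cm3, rel=1e-12)
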