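"""LUT construction, interpolation and the two inversion branches."""

import numpy as np
import pytest

from fingerphantom.errors import (GridError, InvalidParameterError,
                                  NoSolutionError, OutOfRangeError,
                                  UnattainableReflectanceError)
from fingerphantom.mc_transport import Geometry, OpticalPoint, simulate_rt
from fingerphantom.sphere_lut import (LUT, OpticalProperties, ScattererModel,
                                      _subseed, anchor_scatterer, build_lut,
                                      invert_r_fixed, invert_rt,
                                      invert_spectrum, lut_forward,
                                      stitch_slab_series)
from fingerphantom.spectra import Spectrum

GEO = Geometry.cylinder(13.8)


# ---------------------------------------------------------------------------
# build_lut
# ---------------------------------------------------------------------------

def test_build_is_deterministic_and_replayable():
    grids = (np.array([0.05, 0.1, 0.2]), np.array([1.0, 1.5, 2.0]))
    a = build_lut(*grids, GEO, n_photons=3000, max_photons=3000, seed=4)
    b = build_lut(*grids, GEO, n_photons=3000, max_photons=3000, seed=4)
    np.testing.assert_array_equal(a.R_table, b.R_table)
    np.testing.assert_array_equal(a.T_table, b.T_table)
    # single-batch node replays the direct simulation with its sub-seed
    res = simulate_rt(OpticalPoint.from_reduced(0.1, 1.5, n_in=1.4), GEO,
                      n_photons=3000, seed=_subseed(4, 1, 1, 0))
    assert a.R_table[1, 1] == res.R and a.T_table[1, 1] == res.T


def test_degenerate_1x1_lut_equals_single_run():
    lut = build_lut(np.array([0.1]), np.array([1.5]), GEO,
                    n_photons=2000, max_photons=2000, seed=9)
    res = simulate_rt(OpticalPoint.from_reduced(0.1, 1.5, n_in=1.4), GEO,
                      n_photons=2000, seed=_subseed(9, 0, 0, 0))
    assert lut_forward(lut, 0.1, 1.5) == (res.R, res.T)


def test_rejects_nonphysical_grid():
    with pytest.raises(GridError):
        build_lut(np.array([0.0, 0.1]), np.array([1.0, 2.0]), GEO,
                  n_photons=10)
    with pytest.raises(GridError):
        build_lut(np.array([0.2, 0.1]), np.array([1.0, 2.0]), GEO,
                  n_photons=10)


def test_table_monotonicity(small_lut):
    """T falls with mu_a along columns; in the thick regime R rises
    with mu_s' along rows (both beyond 3 standard errors)."""
    T, seT = small_lut.T_table, small_lut.se_T_table
    for j in range(T.shape[1]):
        dT = np.diff(T[:, j])
        tol = 3 * (seT[:-1, j] + seT[1:, j])
        assert np.all(dT <= tol)
    R, seR = small_lut.R_table, small_lut.se_R_table
    i = R.shape[0] // 2  # optically thick mid-grid absorption row
    dR = np.diff(R[i, :])
    tol = 3 * (seR[i, :-1] + seR[i, 1:])
    assert np.all(dR >= -tol)


def test_lut_persistence_round_trip(tmp_path, small_lut):
    p = tmp_path / "lut.npz"
    small_lut.save(p)
    back = LUT.load(p)
    np.testing.assert_array_equal(back.R_table, small_lut.R_table)
    assert back.meta == small_lut.meta


# ---------------------------------------------------------------------------
# lut_forward (analytic tables: interpolation machinery in isolation)
# ---------------------------------------------------------------------------

def test_forward_exact_at_nodes(analytic_lut):
    lut = analytic_lut
    for i, j in [(0, 0), (5, 9), (15, 15)]:
        R, T = lut_forward(lut, lut.mu_a_grid[i], lut.mu_s_reduced_grid[j])
        assert R == lut.R_table[i, j] and T == lut.T_table[i, j]
        Rl, Tl = lut_forward(lut, lut.mu_a_grid[i], lut.mu_s_reduced_grid[j],
                             value_space="log")
        assert Rl == pytest.approx(R, rel=1e-12)


def test_forward_log_midpoint_is_arithmetic_mean(analytic_lut):
    lut = analytic_lut
    i, j = 6, 7
    ma = np.sqrt(lut.mu_a_grid[i] * lut.mu_a_grid[i + 1])
    ms = np.sqrt(lut.mu_s_reduced_grid[j] * lut.mu_s_reduced_grid[j + 1])
    R, T = lut_forward(lut, ma, ms)
    assert R == pytest.approx(lut.R_table[i:i + 2, j:j + 2].mean(), abs=1e-14)
    assert T == pytest.approx(lut.T_table[i:i + 2, j:j + 2].mean(), abs=1e-14)


def test_forward_continuous_across_cells(analytic_lut):
    lut = analytic_lut
    edge = lut.mu_a_grid[8]
    for eps in (1 - 1e-12, 1 + 1e-12):
        R, T = lut_forward(lut, edge * eps, 1.3)
        R0, T0 = lut_forward(lut, edge, 1.3)
        assert abs(R - R0) < 1e-10 and abs(T - T0) < 1e-10


def test_forward_out_of_hull_names_axis(analytic_lut):
    with pytest.raises(OutOfRangeError) as e:
        lut_forward(analytic_lut, 5.0, 1.0)
    assert e.value.axis == "mu_a"
    with pytest.raises(OutOfRangeError) as e:
        lut_forward(analytic_lut, 0.1, 100.0)
    assert e.value.axis == "mu_s_reduced"


def test_coarse_vs_refined_analytic_tables():
    """Interpolating a coarse grid agrees with a 10x finer tabulation of
    the same smooth forward law within 2% at the finger-regime point."""
    def tables(n):
        mu_a = np.geomspace(1e-3, 2, n)
        musr = np.geomspace(0.2, 6, n)
        A, S = np.meshgrid(mu_a, musr, indexing="ij")
        R = 0.5 * S ** 0.3 / np.sqrt(1 + 5 * A)
        T = np.exp(-8.0 * np.sqrt(A * (A + S)))
        z = np.zeros_like(R)
        return LUT(mu_a, musr, R, T, z, z, np.ones_like(R))

    coarse, fine = tables(16), tables(151)
    for vs in ("linear", "log"):
        Rc, Tc = lut_forward(coarse, 0.05, 1.4, value_space=vs)
        Rf, Tf = lut_forward(fine, 0.05, 1.4, value_space=vs)
        assert Rc == pytest.approx(Rf, rel=0.02)
        assert Tc == pytest.approx(Tf, rel=0.02)


# ---------------------------------------------------------------------------
# invert_rt / invert_r_fixed
# ---------------------------------------------------------------------------

def test_invert_recovers_forward_point(cyl_lut):
    R, T = lut_forward(cyl_lut, 0.05, 1.4, value_space="log")
    sol = invert_rt(cyl_lut, R, T)
    assert sol.mu_a == pytest.approx(0.05, rel=1e-6)
    assert sol.mu_s_reduced == pytest.approx(1.4, rel=1e-6)
    assert not sol.on_boundary


def test_invert_round_trip_with_independent_forward(cyl_lut):
    meas = simulate_rt(OpticalPoint.from_reduced(0.03, 1.2, n_in=1.4), GEO,
                       n_photons=500_000, seed=11)
    sol = invert_rt(cyl_lut, meas.R, meas.T)
    assert sol.mu_a == pytest.approx(0.03, rel=0.05)
    assert sol.mu_s_reduced == pytest.approx(1.2, rel=0.05)


def test_invert_rejects_infeasible_pairs(cyl_lut):
    with pytest.raises(NoSolutionError):
        invert_rt(cyl_lut, 0.9, 0.5)
    with pytest.raises(NoSolutionError):
        invert_rt(cyl_lut, 0.0, 0.1)


def test_fixed_branch_consistency(cyl_lut):
    R, _ = lut_forward(cyl_lut, 0.2, 1.4, value_space="log")
    assert invert_r_fixed(cyl_lut, R, 1.4) == pytest.approx(0.2, rel=1e-6)


def test_fixed_branch_unattainable_reflectance(cyl_lut):
    R_top, _ = lut_forward(cyl_lut, cyl_lut.mu_a_grid[0], 1.4,
                           value_space="log")
    with pytest.raises(UnattainableReflectanceError):
        invert_r_fixed(cyl_lut, min(0.999, R_top * 1.5), 1.4)


# ---------------------------------------------------------------------------
# anchoring and spectral dispatch
# ---------------------------------------------------------------------------

def _scatterer(per_unit_700=10.0):
    wl = np.arange(400.0, 1001.0, 50.0)
    return ScattererModel(Spectrum(wl, per_unit_700 * (wl / 700.0) ** -0.6,
                                   kind="generic"))


def test_anchor_ratio_identity_linearity():
    model = _scatterer(10.0)
    c, spec = anchor_scatterer(model, 1.4, 700.0)
    assert c == pytest.approx(0.14)
    assert spec(700.0) == pytest.approx(1.4)  # exact at the anchor
    c2, spec2 = anchor_scatterer(model, 2.8, 700.0)
    assert c2 == pytest.approx(2 * c)
    np.testing.assert_allclose(spec2.values, 2 * spec.values)


def test_anchor_outside_grid_raises():
    with pytest.raises(OutOfRangeError):
        anchor_scatterer(_scatterer(), 1.4, anchor_wavelength=1200.0)


def test_invert_spectrum_dispatch_and_equivalence(cyl_lut):
    """Wavelengths with T below the floor use the fixed branch; the rest
    match wavelength-wise invert_rt exactly."""
    wl = np.array([500.0, 650.0, 800.0])
    truth_mu_a = np.array([0.8, 0.06, 0.03])
    truth_musr = np.array([1.6, 1.45, 1.3])
    R = np.empty(3)
    T = np.empty(3)
    for k in range(3):
        R[k], T[k] = lut_forward(cyl_lut, truth_mu_a[k], truth_musr[k],
                                 value_space="log")
    assert T[0] < 5e-4 < T[1]  # the 500 nm point is in the dark regime
    Rspec = Spectrum(wl, R, kind="reflectance")
    Tspec = Spectrum(wl, T, kind="transmittance")
    pre = Spectrum(wl, truth_musr, kind="mu_s_reduced")
    props = invert_spectrum(cyl_lut, Rspec, Tspec, pre, t_floor=5e-4)
    assert list(props.mode) == ["fixed_mus", "two_channel", "two_channel"]
    np.testing.assert_allclose(props.mu_a.values, truth_mu_a, rtol=1e-5)
    # two-channel wavelengths equal the scalar inverter's answer
    sol = invert_rt(cyl_lut, R[2], T[2])
    assert props.mu_a.values[2] == pytest.approx(sol.mu_a, rel=1e-12)


def test_invert_spectrum_requires_shared_grid(cyl_lut):
    a = Spectrum([500, 600], [0.3, 0.3], kind="reflectance")
    b = Spectrum([500, 700], [0.01, 0.01], kind="transmittance")
    pre = Spectrum([400, 1000], [1.4, 1.4], kind="mu_s_reduced")
    with pytest.raises(GridError):
        invert_spectrum(cyl_lut, a, b, pre)


# ---------------------------------------------------------------------------
# slab-series stitching
# ---------------------------------------------------------------------------

def _props(wl, mu_a, musr):
    return OpticalProperties(
        wavelengths=wl,
        mu_a=Spectrum(wl, mu_a, kind="mu_a"),
        mu_s_reduced=Spectrum(wl, musr, kind="mu_s_reduced"))


def test_stitch_prefers_thickest_valid_slab():
    wl = np.array([650.0])
    per = {d: _props(wl, [0.1 * d], [1.0]) for d in (1.0, 2.0, 4.0, 6.0)}
    T = {1.0: Spectrum(wl, [0.6], kind="transmittance"),
         2.0: Spectrum(wl, [0.3], kind="transmittance"),
         4.0: Spectrum(wl, [0.07], kind="transmittance"),
         6.0: Spectrum(wl, [0.01], kind="transmittance")}
    out = stitch_slab_series(per, T)
    assert out.extras["chosen_thickness_mm"][0] == 4.0
    assert out.mu_a.values[0] == pytest.approx(0.4)
    assert not out.extras["fallback"][0]


def test_stitch_single_thickness_is_identity():
    wl = np.array([600.0, 700.0])
    per = {2.0: _props(wl, [0.1, 0.2], [1.0, 1.1])}
    T = {2.0: Spectrum(wl, [0.5, 0.4], kind="transmittance")}
    out = stitch_slab_series(per, T)
    np.testing.assert_allclose(out.mu_a.values, [0.1, 0.2])
    assert np.all(out.extras["chosen_thickness_mm"] == 2.0)


def test_stitch_fallback_when_all_below_window():
    wl = np.array([450.0])
    per = {d: _props(wl, [1.0], [1.5]) for d in (1.0, 2.0)}
    T = {1.0: Spectrum(wl, [0.01], kind="transmittance"),
         2.0: Spectrum(wl, [1e-4], kind="transmittance")}
    out = stitch_slab_series(per, T)
    assert out.extras["chosen_thickness_mm"][0] == 1.0  # T closest to window
    assert out.extras["fallback"][0]


def test_stitch_empty_input_raises():
    with pytest.raises(InvalidParameterError):
        stitch_slab_series({}, {})
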