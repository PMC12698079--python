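"""Pigment extraction, mixture prediction and recipe fitting."""

import numpy as np
import pytest
from scipy.optimize import nnls

from fingerphantom.errors import (DivisionGuardError, GridError,
                                  InvalidConcentrationError,
                                  InvalidParameterError)
from fingerphantom.pigment_recipe import (PigmentBasis,
                                          extract_specific_absorption,
                                          fit_recipe, mean_relative_error,
                                          predict_mixture_mu_a,
                                          select_significant)
from fingerphantom.spectra import Spectrum
from fingerphantom.synthetic_data import make_pigment_basis

WL = np.arange(400.0, 731.0, 10.0)


def _spec(vals, kind="mu_a"):
    return Spectrum(WL, np.broadcast_to(vals, WL.shape).copy(), kind=kind)


# ---------------------------------------------------------------------------
# specific-absorption extraction
# ---------------------------------------------------------------------------

def test_extraction_arithmetic():
    eps = extract_specific_absorption(_spec(0.50), _spec(0.10), 0.02)
    assert eps.values[0] == pytest.approx(20.0)
    assert eps.kind == "specific_absorption"


def test_extraction_null_pigment_gives_zero():
    s = _spec(0.3)
    eps = extract_specific_absorption(s, s, 0.01)
    assert np.all(eps.values == 0.0)


def test_extraction_is_linear_in_concentration():
    control = _spec(0.1)
    truth = np.linspace(5.0, 25.0, WL.size)
    for c in (0.01, 0.02):
        sample = Spectrum(WL, control.values + c * truth, kind="mu_a")
        eps = extract_specific_absorption(sample, control, c)
        np.testing.assert_allclose(eps.values, truth, atol=1e-12)


def test_extraction_clips_negatives_with_warning():
    with pytest.warns(UserWarning, match="clipped"):
        eps = extract_specific_absorption(_spec(0.05), _spec(0.10), 0.01)
    assert np.all(eps.values == 0.0)


def test_extraction_rejects_bad_concentration():
    with pytest.raises(InvalidConcentrationError):
        extract_specific_absorption(_spec(0.5), _spec(0.1), 0.0)


# ---------------------------------------------------------------------------
# mixture prediction
# ---------------------------------------------------------------------------

def test_predict_identity_unit_and_homogeneity(pigment_fixture):
    basis = pigment_fixture.basis
    baseline = pigment_fixture.baseline
    zero = predict_mixture_mu_a(basis, np.zeros(len(basis)), baseline)
    np.testing.assert_array_equal(zero.values, baseline.values)

    c = np.zeros(len(basis))
    c[2] = 1.0
    one = predict_mixture_mu_a(basis, c, baseline)
    np.testing.assert_allclose(one.values,
                               baseline.values + basis.spectra[2].values)

    ck = pigment_fixture.composition
    p1 = predict_mixture_mu_a(basis, ck, baseline)
    p3 = predict_mixture_mu_a(basis, 3 * ck, baseline)
    np.testing.assert_allclose(p3.values - baseline.values,
                               3 * (p1.values - baseline.values), rtol=1e-12)


def test_predict_rejects_negative_concentration(pigment_fixture):
    c = np.zeros(len(pigment_fixture.basis))
    c[0] = -1e-3
    with pytest.raises(InvalidConcentrationError):
        predict_mixture_mu_a(pigment_fixture.basis, c, pigment_fixture.baseline)


# ---------------------------------------------------------------------------
# recipe fitting
# ---------------------------------------------------------------------------

def test_fit_recovers_exactly_representable_target(pigment_fixture):
    basis = pigment_fixture.basis
    baseline = pigment_fixture.baseline
    truth = np.zeros(len(basis))
    truth[0], truth[2] = 1.0, 0.5
    target = predict_mixture_mu_a(basis, truth, baseline)
    recipe = fit_recipe(basis, target, baseline, n_starts=30, seed=5,
                        bounds=np.full(len(basis), 2.0))
    np.testing.assert_allclose(recipe.concentrations, truth, atol=1e-6)
    assert recipe.chi_squared < 1e-10


def test_best_chi2_non_increasing_in_restarts(pigment_fixture):
    basis = pigment_fixture.basis
    target = pigment_fixture.target
    baseline = pigment_fixture.baseline
    prev = None
    for n in (1, 5, 30):
        chi = fit_recipe(basis, target, baseline, n_starts=n,
                         seed=3).chi_squared
        if prev is not None:
            assert chi <= prev + 1e-18
        prev = chi


def test_multistart_matches_nnls_oracle(pigment_fixture):
    """The bounded problem is convex: the multi-start solution must agree
    with a direct non-negative least-squares solve of the same design."""
    basis = pigment_fixture.basis
    baseline = pigment_fixture.baseline
    rng = np.random.default_rng(8)
    target = Spectrum(basis.wavelengths,
                      baseline.values + basis.matrix
                      @ rng.uniform(0, 0.01, len(basis))
                      + rng.normal(0, 1e-3, basis.wavelengths.size) ** 2,
                      kind="mu_a")
    recipe = fit_recipe(basis, target, baseline, n_starts=30, seed=1)
    _, rnorm = nnls(basis.matrix, target.values - baseline.values)
    assert recipe.chi_squared == pytest.approx(rnorm ** 2, rel=1e-8)


def test_restarts_coincide_on_convex_problem(pigment_fixture):
    """All restarts land on the same optimum for random synthetic targets."""
    basis = pigment_fixture.basis
    baseline = pigment_fixture.baseline
    for k in range(20):
        rng = np.random.default_rng(100 + k)
        c = rng.uniform(0, 0.02, len(basis))
        target = predict_mixture_mu_a(basis, c, baseline)
        chis = [fit_recipe(basis, target, baseline, n_starts=1,
                           seed=s).chi_squared for s in range(30)]
        # the optimum is chi^2 = 0 here, so normalise the spread by the
        # signal energy instead of the (vanishing) optimum itself
        energy = float(np.sum((target.values - baseline.values) ** 2))
        assert (max(chis) - min(chis)) / energy < 1e-6


def test_noise_robust_refit(pigment_fixture):
    """2% multiplicative noise keeps the refit error below 3x the noise."""
    basis = pigment_fixture.basis
    baseline = pigment_fixture.baseline
    clean = pigment_fixture.target
    over = 0
    for s in range(50):
        rng = np.random.default_rng(1000 + s)
        noisy = Spectrum(clean.wavelengths,
                         clean.values * (1 + 0.02 * rng.normal(
                             size=clean.wavelengths.size)), kind="mu_a")
        rec = fit_recipe(basis, noisy, baseline, n_starts=1, seed=s)
        if mean_relative_error(rec.fitted_mu_a, clean) > 6.0:
            over += 1
    assert over == 0


def test_fit_deterministic(pigment_fixture):
    a = fit_recipe(pigment_fixture.basis, pigment_fixture.target,
                   pigment_fixture.baseline, n_starts=5, seed=9)
    b = fit_recipe(pigment_fixture.basis, pigment_fixture.target,
                   pigment_fixture.baseline, n_starts=5, seed=9)
    np.testing.assert_array_equal(a.concentrations, b.concentrations)
    assert a.chi_squared == b.chi_squared


def test_empty_or_mismatched_inputs():
    with pytest.raises(InvalidParameterError):
        PigmentBasis((), ())
    fix = make_pigment_basis(seed=2)
    other = Spectrum(np.arange(500.0, 601.0, 10.0), np.ones(11), kind="mu_a")
    with pytest.raises(GridError):
        fit_recipe(fix.basis, other, fix.baseline)


# ---------------------------------------------------------------------------
# significance pruning
# ---------------------------------------------------------------------------

def test_select_significant_trivial_cases(pigment_fixture):
    basis = pigment_fixture.basis
    baseline = pigment_fixture.baseline
    truth = np.zeros(len(basis))
    truth[1], truth[4] = 0.01, 0.02
    target = predict_mixture_mu_a(basis, truth, baseline)
    rec = fit_recipe(basis, target, baseline, n_starts=5, seed=0)
    assert set(select_significant(rec, basis)) == {1, 4}
    # threshold 0 keeps every pigment with positive concentration
    assert set(select_significant(rec, basis, threshold=0.0)) == \
        set(rec.active_set)


def test_select_significant_recovers_true_five(pigment_fixture):
    rec = fit_recipe(pigment_fixture.basis, pigment_fixture.target,
                     pigment_fixture.baseline, n_starts=30, seed=2)
    kept = select_significant(rec, pigment_fixture.basis, threshold=0.01)
    assert set(kept) == set(pigment_fixture.true_indices)


# ---------------------------------------------------------------------------
# mean relative error
# ---------------------------------------------------------------------------

def test_mean_relative_error_values():
    t = Spectrum([500, 600], [1.0, 1.0], kind="mu_a")
    f = Spectrum([500, 600], [1.1, 0.9], kind="mu_a")
    assert mean_relative_error(t, t) == 0.0
    assert mean_relative_error(f, t) == pytest.approx(10.0)
    # scale invariance
    assert mean_relative_error(f.scaled(3.0), t.scaled(3.0)) == \
        pytest.approx(10.0)


def test_mean_relative_error_zero_guard():
    t = Spectrum([500, 600], [1.0, 0.0], kind="mu_a")
    f = Spectrum([500, 600], [1.0, 0.1], kind="mu_a")
    with pytest.raises(DivisionGuardError):
        mean_relative_error(f, t)
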