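"""Seeded generators for every input the pipeline needs.

No measured finger or pigment data are distributed with the package, so
all stages are exercised on synthetic inputs that emulate the study
conditions: a finger-like ground truth whose transmittance through a
13.8 mm cylinder collapses below 600 nm, a 15-pigment basis of smooth
non-negative absorption spectra of which a known subset of 5 composes
the target, a ZrO2-like scatterer whose spectral slope is shallower
than the tissue-like truth (reproducing the short-wavelength caveat of
the fixed-mu_s' branch), and slab series at 1/2/4/6 mm.

Every generator is a pure function of its seed and parameters; truth
spectra are parametric families, never digitised curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError, InvalidParameterError
from .mc_transport import (DEFAULT_G, BeamConfig, Geometry, SphereConfig,
                           OpticalPoint, simulate_rt)
from .pigment_recipe import PigmentBasis
from .sphere_lut import OpticalProperties, ScattererModel, _subseed
from .spectra import Spectrum

__all__ = [
    "SyntheticTruth", "PigmentFixture", "make_finger_truth",
    "make_pigment_basis", "make_scatterer_model", "add_noise",
    "forward_spectra", "make_slab_series",
]

#: measured finger thickness emulated by the cylinder diameter (mm)
FINGER_DIAMETER_MM = 13.8


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth optical properties plus generation metadata."""

    properties: OpticalProperties
    params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def wavelengths(self) -> np.ndarray:
        return self.properties.wavelengths


@dataclass(frozen=True)
class PigmentFixture:
    """A synthetic basis with a known composed target."""

    basis: PigmentBasis
    composition: np.ndarray  # true concentrations, one per basis member
    target: Spectrum
    baseline: Spectrum
    true_indices: tuple[int, ...]


def _gauss(x, mu, sig):
    return np.exp(-0.5 * ((x - mu) / sig) ** 2)


def make_finger_truth(seed: int = 0, grid=None) -> SyntheticTruth:
    """Finger-like ground truth on a wavelength grid within 400-1000 nm.

    mu_a is a smooth positive baseline plus 2-3 absorption bands and a
    logistic shelf below 600 nm (so that transmittance through the
    13.8 mm cylinder collapses there, as for real tissue whose blood
    absorption dominates the short visible range); mu_s' follows the
    tissue-like power law a (lambda/700)^-b with a in [1, 2] mm^-1 and
    b in [0.5, 1.5]; g = 0.75, n = 1.4.
    """
    wl = np.asarray(grid if grid is not None else np.arange(400.0, 1001.0, 5.0),
                    dtype=float)
    if wl[0] < 400.0 or wl[-1] > 1000.0:
        raise GridError("grid must lie within 400-1000 nm")
    rng = np.random.default_rng(seed)

    a = rng.uniform(1.0, 2.0)
    b = rng.uniform(0.5, 1.5)
    musr = a * (wl / 700.0) ** (-b)

    base = rng.uniform(0.02, 0.05)
    slope = rng.uniform(0.1, 0.5)
    mu_a = base * (wl / 700.0) ** (-slope)
    n_bands = rng.integers(2, 4)
    bands = []
    for _ in range(int(n_bands)):
        amp = rng.uniform(0.5, 1.2)
        mu = rng.uniform(430.0, 565.0)
        sig = rng.uniform(15.0, 35.0)
        bands.append((amp, mu, sig))
        mu_a = mu_a + amp * _gauss(wl, mu, sig)
    shelf = rng.uniform(0.3, 0.45)
    mu_a = mu_a + shelf / (1.0 + np.exp((wl - 590.0) / 12.0))
    # keep the composed absorption within a finger-realistic ceiling
    # (overlapping bands could otherwise stack to implausible values)
    peak = float(mu_a.max())
    if peak > 1.8:
        mu_a *= 1.8 / peak

    props = OpticalProperties(
        wavelengths=wl,
        mu_a=Spectrum(wl, mu_a, kind="mu_a", name="mu_a_truth"),
        mu_s_reduced=Spectrum(wl, musr, kind="mu_s_reduced",
                              name="mus_reduced_truth"),
        g=DEFAULT_G, n=1.4)
    params = {"musr_700": a, "musr_exponent": b, "mu_a_base": base,
              "bands": bands, "shelf": shelf}
    return SyntheticTruth(properties=props, params=params, seed=seed)


def make_pigment_basis(n_pigments: int = 15, seed: int = 0, grid=None,
                       n_true: int = 5, baseline: Spectrum | None = None
                       ) -> PigmentFixture:
    """Synthetic pigment basis with a target composed of ``n_true`` members.

    Each basis member is 1-3 Gaussian absorption bands with seeded
    centres/widths/amplitudes (non-negative by construction); the target
    is the baseline plus a known positive combination of exactly
    ``n_true`` members, returned alongside the composition vector.
    """
    if n_pigments < n_true:
        raise InvalidParameterError(f"need at least {n_true} pigments")
    wl = np.asarray(grid if grid is not None else np.arange(400.0, 731.0, 5.0),
                    dtype=float)
    rng = np.random.default_rng(seed)

    spectra = []
    names = []
    for k in range(n_pigments):
        vals = np.zeros_like(wl)
        for _ in range(int(rng.integers(1, 4))):
            amp = rng.uniform(5.0, 30.0)
            mu = rng.uniform(wl[0], wl[-1])
            sig = rng.uniform(20.0, 80.0)
            vals += amp * _gauss(wl, mu, sig)
        spectra.append(Spectrum(wl, vals, kind="specific_absorption",
                                name=f"pigment_{k:02d}"))
        names.append(f"pigment_{k:02d}")
    # characterised at ~1% preconcentration dilutions
    extraction = tuple(float(c) for c in rng.uniform(0.005, 0.02, n_pigments))
    basis = PigmentBasis(tuple(names), tuple(spectra), extraction)

    if baseline is None:
        baseline = Spectrum(wl, 0.01 + 0.01 * (wl / 700.0) ** (-1.0),
                            kind="mu_a", name="matrix_baseline")
    true_idx = tuple(int(i) for i in rng.choice(n_pigments, n_true,
                                                replace=False))
    composition = np.zeros(n_pigments)
    composition[list(true_idx)] = rng.uniform(0.002, 0.02, n_true)
    target = Spectrum(wl, baseline.values + basis.matrix @ composition,
                      kind="mu_a", name="target_mu_a")
    return PigmentFixture(basis=basis, composition=composition, target=target,
                          baseline=baseline, true_indices=tuple(sorted(true_idx)))


def make_scatterer_model(seed: int = 0, grid=None,
                         exponent: float = 0.6) -> ScattererModel:
    """ZrO2-like per-unit-concentration mu_s' spectrum.

    A power law with a shallower spectral slope (default exponent 0.6)
    than the tissue-like truth, so a model anchored at 700 nm drifts
    from the truth toward short wavelengths, as real particle
    scatterers do against tissue.
    """
    wl = np.asarray(grid if grid is not None else np.arange(400.0, 1001.0, 5.0),
                    dtype=float)
    rng = np.random.default_rng(seed)
    per_unit_700 = rng.uniform(8.0, 15.0)  # mm^-1 per unit mass fraction
    vals = per_unit_700 * (wl / 700.0) ** (-exponent)
    return ScattererModel(Spectrum(wl, vals, kind="generic",
                                   name="zro2_like_per_unit_mus"))


def add_noise(spectrum: Spectrum, relative_sd: float = 0.01,
              floor_sd: float = 1e-4, seed: int = 0) -> Spectrum:
    """Multiplicative-plus-floor Gaussian measurement noise.

    value -> value (1 + e1) + e2 with e1 ~ N(0, relative_sd) and
    e2 ~ N(0, floor_sd); reflectance/transmittance outputs are clipped
    to [0, 1].  Zero noise parameters reproduce the input exactly.
    """
    if relative_sd < 0 or floor_sd < 0:
        raise InvalidParameterError("noise magnitudes must be >= 0")
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, 1.0, len(spectrum)) * relative_sd
    e2 = rng.normal(0.0, 1.0, len(spectrum)) * floor_sd
    vals = spectrum.values * (1.0 + e1) + e2
    if spectrum.kind in ("reflectance", "transmittance"):
        vals = np.clip(vals, 0.0, 1.0)
    return Spectrum(spectrum.wavelengths, vals, kind=spectrum.kind,
                    name=spectrum.name)


def forward_spectra(properties: OpticalProperties, geometry: Geometry,
                    beam: BeamConfig | None = None,
                    sphere: SphereConfig | None = None,
                    n_photons: int = 100_000, seed: int = 0
                    ) -> tuple[Spectrum, Spectrum]:
    """Forward-model R(lambda), T(lambda) for a property set.

    One Monte-Carlo run per wavelength with a stable per-wavelength
    sub-seed.
    """
    wl = properties.wavelengths
    R = np.empty(wl.size)
    T = np.empty(wl.size)
    for k, lam in enumerate(wl):
        optics = OpticalPoint.from_reduced(
            float(properties.mu_a.values[k]),
            float(properties.mu_s_reduced.values[k]),
            g=properties.g, n_in=properties.n_at(lam))
        res = simulate_rt(optics, geometry, beam, sphere,
                          n_photons=n_photons, seed=_subseed(seed, k))
        R[k], T[k] = res.R, res.T
    return (Spectrum(wl, R, kind="reflectance", name="R_forward"),
            Spectrum(wl, T, kind="transmittance", name="T_forward"))


def make_slab_series(truth: SyntheticTruth, thicknesses=(1.0, 2.0, 4.0, 6.0),
                     slab_diameter: float = 35.0,
                     beam: BeamConfig | None = None,
                     sphere: SphereConfig | None = None,
                     n_photons: int = 50_000, seed: int = 0
                     ) -> dict[float, tuple[Spectrum, Spectrum]]:
    """Forward-modelled (R, T) spectra for slabs of several thicknesses."""
    thicknesses = [float(d) for d in thicknesses]
    if any(d <= 0 for d in thicknesses) or \
            any(b <= a for a, b in zip(thicknesses, thicknesses[1:])):
        raise InvalidParameterError("thicknesses must be positive and increasing")
    out = {}
    for m, d in enumerate(thicknesses):
        geo = Geometry.slab(d, diameter=slab_diameter)
        out[d] = forward_spectra(truth.properties, geo, beam, sphere,
                                 n_photons=n_photons, seed=_subseed(seed, m))
    return out
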