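"""Pigment specific-absorption extraction and recipe fitting.

A phantom's absorption spectrum is composed from a basis of pigment
specific-absorption spectra (absorption per unit mass fraction,
characterised once from preconcentration samples) on top of the
baseline absorption of the silicone matrix and the scatterer.  Fitting
a recipe is a bounded non-negative least-squares problem solved from
many random starting points, keeping the lowest-chi^2 solution; the
problem is convex, so all restarts should coincide (asserted by a
direct NNLS oracle in the tests).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .errors import (DivisionGuardError, GridError, InvalidConcentrationError,
                     InvalidParameterError)
from .spectra import Spectrum

__all__ = [
    "PigmentBasis", "Recipe", "extract_specific_absorption",
    "predict_mixture_mu_a", "fit_recipe", "select_significant",
    "mean_relative_error",
]


@dataclass(frozen=True)
class PigmentBasis:
    """Per-pigment specific absorption spectra on a shared grid.

    ``extraction_concentrations`` (mass fractions used when the basis
    was characterised) inform the default fitting bounds.
    """

    names: tuple[str, ...]
    spectra: tuple[Spectrum, ...]
    extraction_concentrations: tuple[float, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "spectra", tuple(self.spectra))
        if len(self.names) != len(self.spectra) or not self.names:
            raise InvalidParameterError("basis needs one name per spectrum")
        if len(set(self.names)) != len(self.names):
            raise InvalidParameterError("pigment names must be unique")
        wl = self.spectra[0].wavelengths
        for s in self.spectra:
            if not np.array_equal(s.wavelengths, wl):
                raise GridError("basis spectra must share the wavelength grid")
            if s.values.min() < 0:
                raise InvalidParameterError("specific absorption must be >= 0")
        if self.extraction_concentrations is not None:
            ec = tuple(float(c) for c in self.extraction_concentrations)
            if len(ec) != len(self.names) or any(c <= 0 for c in ec):
                raise InvalidConcentrationError(
                    "extraction concentrations must be positive, one per pigment")
            object.__setattr__(self, "extraction_concentrations", ec)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    @property
    def matrix(self) -> np.ndarray:
        """Design matrix, wavelengths x pigments."""
        return np.column_stack([s.values for s in self.spectra])

    def resample(self, grid) -> "PigmentBasis":
        return PigmentBasis(self.names,
                            tuple(s.resample(grid) for s in self.spectra),
                            self.extraction_concentrations)

    def subset(self, indices) -> "PigmentBasis":
        idx = list(indices)
        ec = None if self.extraction_concentrations is None else \
            tuple(self.extraction_concentrations[i] for i in idx)
        return PigmentBasis(tuple(self.names[i] for i in idx),
                            tuple(self.spectra[i] for i in idx), ec)

    # -- directory-of-CSVs persistence --------------------------------

    def to_directory(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = []
        for k, (name, spec) in enumerate(zip(self.names, self.spectra)):
            fname = f"pigment_{k:02d}.csv"
            spec.to_csv(path / fname)
            entry = {"name": name, "file": fname}
            if self.extraction_concentrations is not None:
                entry["extraction_concentration"] = \
                    self.extraction_concentrations[k]
            manifest.append(entry)
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_directory(cls, path) -> "PigmentBasis":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        names = [e["name"] for e in manifest]
        spectra = [Spectrum.from_csv(path / e["file"],
                                     kind="specific_absorption", name=e["name"])
                   for e in manifest]
        ec = [e.get("extraction_concentration") for e in manifest]
        ec = None if any(c is None for c in ec) else tuple(ec)
        return cls(tuple(names), tuple(spectra), ec)


@dataclass(frozen=True)
class Recipe:
    """A fitted set of pigment concentrations and its goodness of fit."""

    names: tuple[str, ...]
    concentrations: np.ndarray
    chi_squared: float
    n_starts: int
    seed: int
    active_set: tuple[int, ...]
    fitted_mu_a: Spectrum
    baseline: Spectrum
    meta: dict = field(default_factory=dict, compare=False)

    def to_json(self, path) -> None:
        payload = {
            "names": list(self.names),
            "concentrations": [float(c) for c in self.concentrations],
            "chi_squared": float(self.chi_squared),
            "n_starts": self.n_starts, "seed": self.seed,
            "active_set": list(self.active_set),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def extract_specific_absorption(mu_a_sample: Spectrum, mu_a_control: Spectrum,
                                concentration: float) -> Spectrum:
    """Specific absorption from a preconcentration measurement.

    epsilon(lambda) = (mu_a,sample - mu_a,control) / concentration;
    negative values (measurement noise) are clipped to zero with a
    warning giving the affected wavelength count.
    """
    if concentration <= 0:
        raise InvalidConcentrationError("concentration must be positive")
    if not np.array_equal(mu_a_sample.wavelengths, mu_a_control.wavelengths):
        raise GridError("sample and control must share the wavelength grid")
    eps = (mu_a_sample.values - mu_a_control.values) / concentration
    n_neg = int(np.sum(eps < 0))
    if n_neg:
        warnings.warn(f"clipped {n_neg} negative specific-absorption values "
                      "to zero", stacklevel=2)
        eps = np.maximum(eps, 0.0)
    return Spectrum(mu_a_sample.wavelengths, eps, kind="specific_absorption")


def predict_mixture_mu_a(basis: PigmentBasis, concentrations,
                         baseline: Spectrum) -> Spectrum:
    """Absorption of a mixture: baseline plus the weighted basis sum."""
    c = np.asarray(concentrations, dtype=float)
    if c.shape != (len(basis),):
        raise InvalidParameterError(
            f"need {len(basis)} concentrations, got shape {c.shape}")
    if np.any(c < 0):
        raise InvalidConcentrationError("concentrations must be non-negative")
    if not np.array_equal(basis.wavelengths, baseline.wavelengths):
        raise GridError("basis and baseline must share the wavelength grid")
    return Spectrum(basis.wavelengths, baseline.values + basis.matrix @ c,
                    kind="mu_a", name="fitted_mu_a")


def _default_bounds(basis: PigmentBasis, target: Spectrum,
                    baseline: Spectrum) -> np.ndarray:
    if basis.extraction_concentrations is not None:
        return np.full(len(basis), 10.0 * max(basis.extraction_concentrations))
    # fallback: 10x the single-pigment concentration that would explain
    # the full target excess at each pigment's peak
    excess = max(float(np.max(target.values - baseline.values)), 0.0) or 1.0
    peaks = np.maximum(basis.matrix.max(axis=0), 1e-12)
    return 10.0 * excess / peaks


def fit_recipe(basis: PigmentBasis, target: Spectrum, baseline: Spectrum,
               n_starts: int = 30, seed: int = 0,
               bounds=None, weights=None) -> Recipe:
    """Fit non-negative pigment concentrations to a target absorption.

    Bounded least squares (chi^2 = sum over the grid of squared
    fitted-minus-target residuals, optionally weighted) started from
    ``n_starts`` seeded uniform-random points within the bounds; the
    lowest-chi^2 solution wins.  Deterministic given (seed, n_starts).
    """
    if len(basis) == 0:
        raise InvalidParameterError("empty basis")
    if n_starts < 1:
        raise InvalidParameterError("n_starts must be >= 1")
    for s in (target, baseline):
        if not np.array_equal(s.wavelengths, basis.wavelengths):
            raise GridError("target/baseline must share the basis grid")
    M = basis.matrix
    y = target.values - baseline.values
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    if w.shape != y.shape or np.any(w < 0):
        raise InvalidParameterError("weights must be non-negative, one per "
                                    "wavelength")
    ub = np.asarray(bounds, float) if bounds is not None else \
        _default_bounds(basis, target, baseline)
    if ub.ndim == 0:
        ub = np.full(len(basis), float(ub))

    Mw = M * w[:, None]
    yw = y * w

    def chi2(c):
        r = Mw @ c - yw
        return float(r @ r)

    def grad(c):
        return 2.0 * (Mw.T @ (Mw @ c - yw))

    rng = np.random.default_rng(seed)
    box = [(0.0, float(u)) for u in ub]
    best_c, best_chi = None, np.inf
    for _ in range(n_starts):
        c0 = rng.uniform(0.0, ub)
        res = minimize(chi2, c0, jac=grad, method="L-BFGS-B", bounds=box,
                       options={"ftol": 1e-18, "gtol": 1e-14, "maxiter": 2000})
        if res.fun < best_chi:
            best_chi, best_c = float(res.fun), np.asarray(res.x)
    best_c = np.maximum(best_c, 0.0)
    fitted = predict_mixture_mu_a(basis, best_c, baseline)
    active = tuple(int(i) for i in np.flatnonzero(best_c > 0))
    return Recipe(names=basis.names, concentrations=best_c,
                  chi_squared=chi2(best_c), n_starts=n_starts, seed=seed,
                  active_set=active, fitted_mu_a=fitted, baseline=baseline,
                  meta={"bounds": [float(u) for u in ub]})


def select_significant(recipe: Recipe, basis: PigmentBasis,
                       threshold: float = 0.01) -> tuple[int, ...]:
    """Indices of pigments that contribute materially to the fit.

    Pigment i is kept iff max over wavelengths of c_i eps_i(lambda)
    divided by the total pigment contribution (fitted - baseline) at
    that wavelength reaches ``threshold``.  Intended to be followed by
    a refit on the kept subset.
    """
    M = basis.matrix
    c = recipe.concentrations
    total = recipe.fitted_mu_a.values - recipe.baseline.values
    ok = total > 0
    kept = []
    for i in range(len(basis)):
        contrib = c[i] * M[:, i]
        frac = np.zeros_like(total)
        frac[ok] = contrib[ok] / total[ok]
        if frac.max(initial=0.0) >= threshold and c[i] > 0:
            kept.append(i)
    return tuple(kept)


def mean_relative_error(fitted: Spectrum, target: Spectrum) -> float:
    """Mean over wavelengths of |fitted - target| / target, in percent."""
    if not np.array_equal(fitted.wavelengths, target.wavelengths):
        raise GridError("fitted and target must share the wavelength grid")
    if np.any(target.values == 0):
        raise DivisionGuardError("target contains zeros; relative error "
                                 "undefined")
    return float(np.mean(np.abs(fitted.values - target.values)
                         / np.abs(target.values)) * 100.0)
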