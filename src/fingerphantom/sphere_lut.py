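"""Look-up-table forward model and the (R, T) -> (mu_a, mu_s') inversion.

The LUT tabulates integrating-sphere reflectance and transmittance from
the Monte-Carlo forward model on log-spaced coefficient grids for one
fixed geometry.  Inversion is a per-wavelength fit of the interpolated
forward model to measured fractions:

* both channels available -> 2-D minimisation of squared relative
  residuals (coarse grid scan, then Nelder-Mead refinement);
* transmittance below the measurement floor (the sub-600 nm regime of a
  finger-thick sample) -> 1-D root solve for mu_a at a predefined
  mu_s'(lambda) taken from the anchored scatterer model.

Interpolation is bilinear in (log mu_a, log mu_s').  The default value
space is linear; the inverters interpolate T in log value space, where
its near-exponential decay with absorption is close to planar and the
cell-midpoint bias stays small even on a coarse 16x16 grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq, minimize

from .errors import (GridError, InvalidParameterError, NoSolutionError,
                     OutOfRangeError, UnattainableReflectanceError)
from .mc_transport import (DEFAULT_G, BeamConfig, Geometry, OpticalPoint,
                           SphereConfig, simulate_rt)
from .spectra import Spectrum

__all__ = [
    "LUT", "ScattererModel", "OpticalProperties", "InversionResult",
    "default_grids", "build_lut", "lut_forward", "invert_rt",
    "invert_r_fixed", "anchor_scatterer", "invert_spectrum",
    "stitch_slab_series",
]

#: log-T floor: tabulated fractions below this are clamped before taking logs
_LOG_FLOOR = 1e-30


def default_grids(n_mu_a: int = 16, n_musr: int = 16,
                  mu_a_min: float = 1e-3, mu_a_max: float = 2.0,
                  musr_min: float = 0.2, musr_max: float = 6.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Default log-spaced coefficient grids (mm^-1), finger-regime ranges."""
    return (np.geomspace(mu_a_min, mu_a_max, n_mu_a),
            np.geomspace(musr_min, musr_max, n_musr))


def _subseed(seed: int, *indices: int) -> int:
    """Stable splitmix-style sub-stream seed below 2^63."""
    mask = (1 << 64) - 1
    z = (int(seed) + 0x9E3779B97F4A7C15) & mask
    for k in indices:
        z ^= (int(k) * 0xD1B54A32D192ED03) & mask
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        z ^= z >> 31
    return z >> 1


@dataclass
class LUT:
    """Forward-model tables R(mu_a, mu_s') and T(mu_a, mu_s').

    Tables are indexed ``[i, j]`` over ``(mu_a_grid, mu_s_reduced_grid)``
    with standard-error companions; metadata records everything needed
    to rebuild the tables bit-identically.
    """

    mu_a_grid: np.ndarray
    mu_s_reduced_grid: np.ndarray
    R_table: np.ndarray
    T_table: np.ndarray
    se_R_table: np.ndarray
    se_T_table: np.ndarray
    n_photons_table: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = (len(self.mu_a_grid), len(self.mu_s_reduced_grid))
        for name in ("R_table", "T_table", "se_R_table", "se_T_table",
                     "n_photons_table"):
            if getattr(self, name).shape != shape:
                raise GridError(f"{name} shape must be {shape}")

    # -- persistence: named arrays + a JSON metadata block ------------

    def save(self, path) -> None:
        np.savez(path,
                 mu_a_grid=self.mu_a_grid,
                 mu_s_reduced_grid=self.mu_s_reduced_grid,
                 R_table=self.R_table, T_table=self.T_table,
                 se_R_table=self.se_R_table, se_T_table=self.se_T_table,
                 n_photons_table=self.n_photons_table,
                 meta_json=np.array(json.dumps(self.meta)))

    @classmethod
    def load(cls, path) -> "LUT":
        with np.load(path, allow_pickle=False) as z:
            return cls(z["mu_a_grid"], z["mu_s_reduced_grid"],
                       z["R_table"], z["T_table"],
                       z["se_R_table"], z["se_T_table"],
                       z["n_photons_table"],
                       meta=json.loads(str(z["meta_json"])))


@dataclass(frozen=True)
class ScattererModel:
    """mu_s' contributed per unit scatterer concentration.

    Models the ZrO2 particle dispersion used to set the phantom's
    scattering; ``metadata`` carries informational particle-size
    percentiles (d10/d50/d90 in micrometres).
    """

    spectrum: Spectrum
    metadata: dict = field(default_factory=lambda: {
        "d10_um": 0.131, "d50_um": 0.871, "d90_um": 3.228})

    def __post_init__(self):
        if np.any(self.spectrum.values <= 0):
            raise InvalidParameterError(
                "scatterer model values must be strictly positive")


@dataclass
class OpticalProperties:
    """Wavelength-resolved (mu_a, mu_s') with anisotropy and index.

    ``mode`` records, per wavelength, whether both channels were used
    (``two_channel``) or the fixed-mu_s' branch (``fixed_mus``).
    """

    wavelengths: np.ndarray
    mu_a: Spectrum
    mu_s_reduced: Spectrum
    g: float = DEFAULT_G
    n: float | Spectrum = 1.4
    mode: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for s in (self.mu_a, self.mu_s_reduced):
            if not np.array_equal(s.wavelengths, self.wavelengths):
                raise GridError("member spectra must share the wavelength grid")
        if self.mode is None:
            self.mode = np.full(self.wavelengths.size, "two_channel")
        self.mode = np.asarray(self.mode)
        if self.mode.size != self.wavelengths.size:
            raise GridError("mode flags must match the wavelength grid")

    def n_at(self, wavelength: float) -> float:
        if isinstance(self.n, Spectrum):
            return float(self.n(wavelength))
        return float(self.n)


@dataclass(frozen=True)
class InversionResult:
    """One wavelength's inverse solution with its fit diagnostics."""

    mu_a: float
    mu_s_reduced: float
    residual: float
    on_boundary: bool = False

    def __iter__(self):
        return iter((self.mu_a, self.mu_s_reduced))


# ---------------------------------------------------------------------------
# LUT construction
# ---------------------------------------------------------------------------

def build_lut(mu_a_grid, mu_s_reduced_grid, geometry: Geometry,
              beam: BeamConfig | None = None,
              sphere: SphereConfig | None = None,
              g: float = DEFAULT_G, n: float = 1.4, n_out: float = 1.0,
              n_photons: int = 50_000, seed: int = 0,
              refine_rel_se: float = 0.1, max_photons: int = 800_000,
              progress: bool = False) -> LUT:
    """Tabulate the Monte-Carlo forward model on coefficient grids.

    Each node starts with ``n_photons`` packets and is refined in equal
    batches (stable per-batch sub-seeds) until the relative standard
    errors of both R and T drop below ``refine_rel_se`` or ``max_photons``
    is reached.  High-absorption nodes, whose T is tiny, are exactly the
    cheap ones, so refinement concentrates where it is affordable.
    Rebuilding with the same arguments is bit-identical.
    """
    mu_a_grid = np.asarray(mu_a_grid, dtype=float)
    mu_s_reduced_grid = np.asarray(mu_s_reduced_grid, dtype=float)
    for name, grid in (("mu_a_grid", mu_a_grid),
                       ("mu_s_reduced_grid", mu_s_reduced_grid)):
        if grid.size < 2 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
            if grid.size != 1:  # 1x1 degenerate grids are allowed
                raise GridError(f"{name} must be strictly increasing and positive")
        if grid[0] <= 0:
            raise GridError(f"{name} must cover physical (positive) values")
    beam = beam or BeamConfig()
    sphere = sphere or SphereConfig()

    shape = (mu_a_grid.size, mu_s_reduced_grid.size)
    R = np.zeros(shape)
    T = np.zeros(shape)
    seR = np.zeros(shape)
    seT = np.zeros(shape)
    nph = np.zeros(shape)
    for i, mu_a in enumerate(mu_a_grid):
        for j, musr in enumerate(mu_s_reduced_grid):
            optics = OpticalPoint.from_reduced(mu_a, musr, g=g,
                                               n_in=n, n_out=n_out)
            sum_r = sum_t = sum_r2 = sum_t2 = 0.0
            total = 0
            batch = 0
            while True:
                res = simulate_rt(optics, geometry, beam, sphere,
                                  n_photons=n_photons,
                                  seed=_subseed(seed, i, j, batch))
                # de-normalise to combine batches exactly
                sum_r += res.R * n_photons
                sum_t += res.T * n_photons
                sum_r2 += (res.se_R ** 2 * n_photons + res.R ** 2) * n_photons
                sum_t2 += (res.se_T ** 2 * n_photons + res.T ** 2) * n_photons
                total += n_photons
                batch += 1
                mR, mT = sum_r / total, sum_t / total
                se_r = math.sqrt(max(0.0, sum_r2 / total - mR * mR) / total)
                se_t = math.sqrt(max(0.0, sum_t2 / total - mT * mT) / total)
                ok_r = mR <= 0 or se_r <= refine_rel_se * mR
                ok_t = mT <= 0 or se_t <= refine_rel_se * mT
                if (ok_r and ok_t) or total + n_photons > max_photons:
                    break
            R[i, j], T[i, j] = mR, mT
            seR[i, j], seT[i, j] = se_r, se_t
            nph[i, j] = total
        if progress:
            print(f"  lut row {i + 1}/{mu_a_grid.size} (mu_a={mu_a:.4g})")

    meta = {
        "geometry": asdict(geometry), "beam": asdict(beam),
        "sphere": asdict(sphere), "g": g, "n": n, "n_out": n_out,
        "n_photons": n_photons, "seed": seed,
        "refine_rel_se": refine_rel_se, "max_photons": max_photons,
    }
    return LUT(mu_a_grid, mu_s_reduced_grid, R, T, seR, seT, nph, meta=meta)


# ---------------------------------------------------------------------------
# Forward interpolation
# ---------------------------------------------------------------------------

def _locate(grid: np.ndarray, value: float, axis: str) -> tuple[int, float]:
    if value < grid[0] * (1 - 1e-12) or value > grid[-1] * (1 + 1e-12):
        raise OutOfRangeError(
            f"{axis}={value:g} outside LUT hull [{grid[0]:g}, {grid[-1]:g}]",
            axis=axis)
    lg = np.log(grid)
    lv = math.log(value)
    i = int(np.clip(np.searchsorted(lg, lv) - 1, 0, grid.size - 2))
    f = (lv - lg[i]) / (lg[i + 1] - lg[i])
    return i, float(np.clip(f, 0.0, 1.0))


def _bilinear(table: np.ndarray, i: int, j: int, fx: float, fy: float,
              log_values: bool) -> float:
    cell = table[i:i + 2, j:j + 2]
    if log_values:
        cell = np.log(np.maximum(cell, _LOG_FLOOR))
    v = (cell[0, 0] * (1 - fx) * (1 - fy) + cell[0, 1] * (1 - fx) * fy
         + cell[1, 0] * fx * (1 - fy) + cell[1, 1] * fx * fy)
    return math.exp(v) if log_values else float(v)


def lut_forward(lut: LUT, mu_a: float, mu_s_reduced: float,
                value_space: str = "linear") -> tuple[float, float]:
    """Interpolated (R, T) at a coefficient pair inside the grid hull.

    Bilinear in (log mu_a, log mu_s'), exact at nodes.  With
    ``value_space="log"`` the fractions themselves are interpolated in
    log space, which tracks the near-exponential decay of T between
    nodes much better; node values are identical in both modes.
    """
    if value_space not in ("linear", "log"):
        raise InvalidParameterError(f"unknown value_space {value_space!r}")
    if lut.mu_a_grid.size == 1 and lut.mu_s_reduced_grid.size == 1:
        return float(lut.R_table[0, 0]), float(lut.T_table[0, 0])
    i, fx = _locate(lut.mu_a_grid, mu_a, "mu_a")
    j, fy = _locate(lut.mu_s_reduced_grid, mu_s_reduced, "mu_s_reduced")
    log_vals = value_space == "log"
    R = _bilinear(lut.R_table, i, j, fx, fy, log_vals)
    T = _bilinear(lut.T_table, i, j, fx, fy, log_vals)
    return R, T


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------

def _forward_grid(lut: LUT, subdiv: int, value_space: str):
    """Dense forward evaluation on a subdivided log grid (vectorised)."""
    la = np.log(lut.mu_a_grid)
    lb = np.log(lut.mu_s_reduced_grid)
    fa = np.linspace(la[0], la[-1], (la.size - 1) * subdiv + 1)
    fb = np.linspace(lb[0], lb[-1], (lb.size - 1) * subdiv + 1)

    def interp2(table):
        vals = np.log(np.maximum(table, _LOG_FLOOR)) \
            if value_space == "log" else table
        ia = np.clip(np.searchsorted(la, fa) - 1, 0, la.size - 2)
        ib = np.clip(np.searchsorted(lb, fb) - 1, 0, lb.size - 2)
        fx = (fa - la[ia]) / (la[ia + 1] - la[ia])
        fy = (fb - lb[ib]) / (lb[ib + 1] - lb[ib])
        fx = np.clip(fx, 0, 1)[:, None]
        fy = np.clip(fy, 0, 1)[None, :]
        v = (vals[np.ix_(ia, ib)] * (1 - fx) * (1 - fy)
             + vals[np.ix_(ia, ib + 1)] * (1 - fx) * fy
             + vals[np.ix_(ia + 1, ib)] * fx * (1 - fy)
             + vals[np.ix_(ia + 1, ib + 1)] * fx * fy)
        return np.exp(v) if value_space == "log" else v

    return fa, fb, interp2(lut.R_table), interp2(lut.T_table)


def invert_rt(lut: LUT, R_meas: float, T_meas: float,
              value_space: str = "log", subdiv: int = 4,
              max_residual: float = 0.25) -> InversionResult:
    """Invert a measured (R, T) pair to (mu_a, mu_s').

    Minimises the sum of squared relative residuals of both channels
    over the grid hull: an exhaustive coarse scan on a subdivided grid
    (ties broken toward smaller mu_a by scan order) followed by
    Nelder-Mead refinement in (log mu_a, log mu_s').  A solution pinned
    to the hull edge carries ``on_boundary``; a residual above
    ``max_residual`` raises :class:`NoSolutionError`.
    """
    if not (0.0 < R_meas < 1.0) or not (0.0 < T_meas < 1.0):
        raise NoSolutionError("R and T must lie strictly in (0, 1)")
    if R_meas + T_meas >= 1.0:
        raise NoSolutionError(f"infeasible input: R + T = {R_meas + T_meas:g} >= 1")

    fa, fb, Rg, Tg = _forward_grid(lut, subdiv, value_space)
    obj_grid = ((Rg - R_meas) / R_meas) ** 2 + ((Tg - T_meas) / T_meas) ** 2
    k = int(np.argmin(obj_grid))  # first minimum: smallest mu_a wins ties
    i0, j0 = divmod(k, fb.size)
    x0 = np.array([fa[i0], fb[j0]])

    lo = np.array([fa[0], fb[0]])
    hi = np.array([fa[-1], fb[-1]])

    def objective(x):
        xc = np.clip(x, lo, hi)
        R, T = lut_forward(lut, math.exp(xc[0]), math.exp(xc[1]), value_space)
        pen = float(np.sum((x - xc) ** 2))
        return ((R - R_meas) / R_meas) ** 2 + ((T - T_meas) / T_meas) ** 2 + pen

    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 2000})
    x = np.clip(res.x, lo, hi)
    residual = objective(x)
    if residual > max_residual:
        raise NoSolutionError(
            f"no admissible solution: residual {residual:.3g} > {max_residual:g}")
    on_edge = bool(np.any(x - lo < 1e-6) or np.any(hi - x < 1e-6))
    return InversionResult(mu_a=math.exp(x[0]), mu_s_reduced=math.exp(x[1]),
                           residual=float(residual), on_boundary=on_edge)


def invert_r_fixed(lut: LUT, R_meas: float, mu_s_reduced_fixed: float,
                   value_space: str = "log") -> float:
    """Absorption from reflectance alone at a predefined mu_s'.

    Solves R(mu_a; mu_s' fixed) = R_meas by bracketing + Brent root
    finding on the interpolated forward model; R is monotone decreasing
    in mu_a over the bracket.
    """
    if not (0.0 < R_meas < 1.0):
        raise NoSolutionError("R must lie strictly in (0, 1)")
    _locate(lut.mu_s_reduced_grid, mu_s_reduced_fixed, "mu_s_reduced")
    la_lo = math.log(lut.mu_a_grid[0])
    la_hi = math.log(lut.mu_a_grid[-1])

    def f(la):
        R, _ = lut_forward(lut, math.exp(la), mu_s_reduced_fixed, value_space)
        return R - R_meas

    f_lo, f_hi = f(la_lo), f(la_hi)
    if f_lo < 0.0:
        raise UnattainableReflectanceError(
            f"R_meas={R_meas:g} exceeds the attainable maximum "
            f"{f_lo + R_meas:g} at mu_s'={mu_s_reduced_fixed:g}")
    if f_hi > 0.0:
        raise UnattainableReflectanceError(
            f"R_meas={R_meas:g} below the attainable minimum "
            f"{f_hi + R_meas:g} at mu_s'={mu_s_reduced_fixed:g}")
    if f_lo == 0.0:
        return float(lut.mu_a_grid[0])
    return float(math.exp(brentq(f, la_lo, la_hi, xtol=1e-14, rtol=1e-14)))


def anchor_scatterer(model: ScattererModel, target_mus_reduced_at_anchor: float,
                     anchor_wavelength: float = 700.0
                     ) -> tuple[float, Spectrum]:
    """Scale the scatterer to match a target mu_s' at the anchor wavelength.

    Returns ``(concentration, predefined mu_s' spectrum)`` with
    ``spectrum(anchor) == target`` exactly: the concentration is the
    ratio of target to the per-unit model at the anchor.
    """
    if target_mus_reduced_at_anchor <= 0:
        raise InvalidParameterError("target mu_s' must be positive")
    per_unit = model.spectrum(anchor_wavelength)  # raises outside grid
    concentration = target_mus_reduced_at_anchor / per_unit
    predefined = Spectrum(model.spectrum.wavelengths,
                          concentration * model.spectrum.values,
                          kind="mu_s_reduced", name="predefined_mus")
    return concentration, predefined


def invert_spectrum(lut: LUT, R: Spectrum, T: Spectrum,
                    predefined_mus: Spectrum, t_floor: float = 5e-4,
                    g: float = DEFAULT_G, n: float = 1.4) -> OpticalProperties:
    """Wavelength-by-wavelength inversion with automatic branch dispatch.

    Uses the two-channel inversion wherever T >= ``t_floor`` and the
    fixed-mu_s' branch (predefined scattering) below it, recording the
    branch per wavelength.  Errors from the per-wavelength inverters
    are re-raised tagged with the offending wavelength.
    """
    if not np.array_equal(R.wavelengths, T.wavelengths):
        raise GridError("R and T must share a wavelength grid")
    wl = R.wavelengths
    mus_pre = predefined_mus(wl)

    mu_a = np.empty(wl.size)
    musr = np.empty(wl.size)
    mode = np.empty(wl.size, dtype="<U12")
    residual = np.zeros(wl.size)
    boundary = np.zeros(wl.size, dtype=bool)
    for k, lam in enumerate(wl):
        try:
            if T.values[k] >= t_floor:
                sol = invert_rt(lut, float(R.values[k]), float(T.values[k]))
                mu_a[k], musr[k] = sol.mu_a, sol.mu_s_reduced
                residual[k] = sol.residual
                boundary[k] = sol.on_boundary
                mode[k] = "two_channel"
            else:
                mu_a[k] = invert_r_fixed(lut, float(R.values[k]), float(mus_pre[k]))
                musr[k] = mus_pre[k]
                mode[k] = "fixed_mus"
        except (NoSolutionError, OutOfRangeError) as exc:
            raise type(exc)(f"at {lam:g} nm: {exc}") from exc
    return OpticalProperties(
        wavelengths=wl,
        mu_a=Spectrum(wl, mu_a, kind="mu_a", name="mu_a_inverted"),
        mu_s_reduced=Spectrum(wl, musr, kind="mu_s_reduced",
                              name="mus_reduced_inverted"),
        g=g, n=n, mode=mode,
        extras={"residual": residual, "on_boundary": boundary,
                "t_floor": t_floor})


def stitch_slab_series(per_thickness: dict[float, OpticalProperties],
                       T_spectra: dict[float, Spectrum],
                       window: tuple[float, float] = (0.05, 0.8)
                       ) -> OpticalProperties:
    """Merge per-thickness slab inversions into one property set.

    Per wavelength the thickest slab whose transmittance lies inside
    ``window`` is selected (thick slabs give the best-conditioned
    measurement); when none qualifies, the slab with T closest to the
    window is used and the wavelength is flagged as a fallback.
    """
    if not per_thickness:
        raise InvalidParameterError("empty thickness map")
    thicknesses = sorted(per_thickness)
    wl = per_thickness[thicknesses[0]].wavelengths
    for d in thicknesses:
        if not np.array_equal(per_thickness[d].wavelengths, wl) or \
                not np.array_equal(T_spectra[d].wavelengths, wl):
            raise GridError("all inputs must share the wavelength grid")
    t_low, t_high = window

    mu_a = np.empty(wl.size)
    musr = np.empty(wl.size)
    mode = np.empty(wl.size, dtype="<U12")
    chosen = np.empty(wl.size)
    fallback = np.zeros(wl.size, dtype=bool)
    for k in range(wl.size):
        pick = None
        for d in thicknesses:  # ascending: the last valid one is thickest
            if t_low <= T_spectra[d].values[k] <= t_high:
                pick = d
        if pick is None:
            fallback[k] = True
            dist = {d: (0.0 if t_low <= T_spectra[d].values[k] <= t_high
                        else min(abs(T_spectra[d].values[k] - t_low),
                                 abs(T_spectra[d].values[k] - t_high)))
                    for d in thicknesses}
            pick = min(thicknesses, key=lambda d: (dist[d], -d))
        props = per_thickness[pick]
        mu_a[k] = props.mu_a.values[k]
        musr[k] = props.mu_s_reduced.values[k]
        mode[k] = props.mode[k]
        chosen[k] = pick
    ref = per_thickness[thicknesses[0]]
    return OpticalProperties(
        wavelengths=wl,
        mu_a=Spectrum(wl, mu_a, kind="mu_a", name="mu_a_stitched"),
        mu_s_reduced=Spectrum(wl, musr, kind="mu_s_reduced",
                              name="mus_reduced_stitched"),
        g=ref.g, n=ref.n, mode=mode,
        extras={"chosen_thickness_mm": chosen, "fallback": fallback,
                "window": window})
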