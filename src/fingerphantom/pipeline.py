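"""End-to-end orchestration: invert, anchor, fit, predict, compare.

The pipeline reproduces the full phantom-design analysis on file-based
inputs: invert measured finger reflectance/transmittance spectra to
optical properties with the cylinder LUT (two-channel where T is
measurable, fixed-mu_s' below the transmittance floor), anchor the
scatterer concentration at 700 nm, fit a pigment recipe to the target
absorption in two stages (full basis, then a refit on the significant
subset), predict the phantom's reflectance from the fitted absorption
and predefined scattering, and report the mean relative error of the
fit and the CIEDE2000 difference between predicted and target
reflectance.

Everything is a pure function of (input files, config, seeds); every
report records the resolved config hash and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .colorimetry import ObserverIlluminant, delta_e_between_spectra
from .errors import ConfigError, NoSolutionError, OutOfRangeError
from .mc_transport import BeamConfig, Geometry, SphereConfig
from .pigment_recipe import (PigmentBasis, fit_recipe, mean_relative_error,
                             select_significant)
from .sphere_lut import (LUT, OpticalProperties, ScattererModel,
                         anchor_scatterer, build_lut, default_grids,
                         invert_spectrum, lut_forward)
from .spectra import Spectrum

log = logging.getLogger("fingerphantom")

__all__ = ["PipelineConfig", "run_inversion", "run_recipe", "run_compare",
           "run_all", "get_or_build_lut"]

_DEFAULTS: dict = {
    "paths": {
        "r_spectrum": None,        # finger reflectance CSV
        "t_spectrum": None,        # finger transmittance CSV
        "basis_dir": None,         # pigment basis directory (manifest.json)
        "scatterer": None,         # per-unit mu_s' CSV
        "lut": None,               # optional prebuilt LUT (.npz)
        "output_dir": "out",
    },
    "geometry": {"kind": "cylinder", "size_mm": 13.8, "length_mm": 60.0},
    "beam": {"diameter_mm": 5.0},
    "sphere": {"sample_port_mm": 25.0, "entrance_port_mm": 10.0,
               "count_specular": False},
    "mc": {"n_photons": 50_000, "seed": 0, "roulette_threshold": 1e-4},
    "lut": {"mu_a_min": 1e-3, "mu_a_max": 2.0, "n_mu_a": 16,
            "musr_min": 0.2, "musr_max": 6.0, "n_musr": 16,
            "max_photons": 400_000, "refine_rel_se": 0.1},
    "invert": {"t_floor": 5e-4, "g": 0.75, "n": 1.4,
               "anchor_nm": 700.0},
    "fit": {"n_starts": 30, "seed": 0, "grid_lo_nm": 400.0,
            "grid_hi_nm": 730.0, "significance_threshold": 0.01},
    "stitch": {"t_low": 0.05, "t_high": 0.8},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclasses.dataclass
class PipelineConfig:
    """Resolved pipeline configuration (defaults merged with user YAML)."""

    raw: dict

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            user = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        return cls(_merge(_DEFAULTS, user))

    @classmethod
    def from_dict(cls, d: dict | None = None) -> "PipelineConfig":
        return cls(_merge(_DEFAULTS, d or {}))

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def validate_paths(self, need=("r_spectrum", "t_spectrum")) -> None:
        """Fail before any compute if a referenced input is missing."""
        for key in need:
            p = self.raw["paths"].get(key)
            if p is None:
                raise ConfigError(f"paths.{key} is required but not set")
            if not Path(p).exists():
                raise ConfigError(f"paths.{key} = {p} does not exist")

    # -- constructed components ---------------------------------------

    @property
    def geometry(self) -> Geometry:
        g = self.raw["geometry"]
        if g["kind"] == "cylinder":
            return Geometry.cylinder(g["size_mm"], g.get("length_mm", 60.0))
        return Geometry.slab(g["size_mm"])

    @property
    def beam(self) -> BeamConfig:
        d = self.raw["beam"]["diameter_mm"]
        return BeamConfig.pencil() if d == 0 else BeamConfig(d)

    @property
    def sphere(self) -> SphereConfig:
        s = self.raw["sphere"]
        return SphereConfig(sample_port_diameter=s["sample_port_mm"],
                            entrance_port_diameter=s["entrance_port_mm"],
                            count_specular=s["count_specular"])

    def output_dir(self) -> Path:
        out = Path(self.raw["paths"]["output_dir"])
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.resolved.yaml").write_text(
            yaml.safe_dump(self.raw, sort_keys=True))
        return out

    def provenance(self) -> dict:
        return {"config_hash": self.digest,
                "mc_seed": self.raw["mc"]["seed"],
                "fit_seed": self.raw["fit"]["seed"]}


def get_or_build_lut(config: PipelineConfig, lut: LUT | None = None) -> LUT:
    """Load the configured LUT or build it from the MC settings."""
    if lut is not None:
        return lut
    path = config["paths"].get("lut")
    if path and Path(path).exists():
        log.info("loading LUT from %s", path)
        return LUT.load(path)
    c = config["lut"]
    grids = default_grids(c["n_mu_a"], c["n_musr"], c["mu_a_min"],
                          c["mu_a_max"], c["musr_min"], c["musr_max"])
    log.info("building %dx%d LUT (this is the expensive step)",
             c["n_mu_a"], c["n_musr"])
    built = build_lut(*grids, config.geometry, config.beam, config.sphere,
                      g=config["invert"]["g"], n=config["invert"]["n"],
                      n_photons=config["mc"]["n_photons"],
                      seed=config["mc"]["seed"],
                      refine_rel_se=c["refine_rel_se"],
                      max_photons=c["max_photons"])
    if path:
        built.save(path)
    return built


def run_inversion(config: PipelineConfig, lut: LUT | None = None,
                  scatterer: ScattererModel | None = None
                  ) -> tuple[OpticalProperties, dict]:
    """Invert finger R/T spectra to optical properties; write reports.

    A first two-channel pass over the measurable-T range pins mu_s' at
    the anchor wavelength; the scatterer model is scaled to match it
    there, providing the predefined mu_s' for the fixed branch; the
    full spectrum is then inverted with automatic branch dispatch.
    """
    config.validate_paths(("r_spectrum", "t_spectrum"))
    if scatterer is None:
        config.validate_paths(("scatterer",))
        scatterer = ScattererModel(Spectrum.from_csv(
            config["paths"]["scatterer"], kind="generic"))
    R = Spectrum.from_csv(config["paths"]["r_spectrum"], kind="reflectance")
    T = Spectrum.from_csv(config["paths"]["t_spectrum"], kind="transmittance")
    lut = get_or_build_lut(config, lut)
    inv = config["invert"]
    anchor = float(inv["anchor_nm"])

    # pass 1: mu_s' at the anchor from the two-channel branch alone
    from .sphere_lut import invert_rt  # local import keeps module API slim
    iA = int(np.argmin(np.abs(R.wavelengths - anchor)))
    if T.values[iA] < inv["t_floor"]:
        raise NoSolutionError(
            f"transmittance at the {anchor:g} nm anchor is below the floor; "
            "cannot anchor the scatterer")
    sol = invert_rt(lut, float(R.values[iA]), float(T.values[iA]))
    concentration, predefined = anchor_scatterer(scatterer, sol.mu_s_reduced,
                                                 anchor)
    log.info("scatterer anchored: mu_s'(%g nm)=%.3f mm^-1, concentration %.4g",
             anchor, sol.mu_s_reduced, concentration)

    props = invert_spectrum(lut, R, T, predefined, t_floor=inv["t_floor"],
                            g=inv["g"], n=inv["n"])

    out = config.output_dir()
    props.mu_a.to_csv(out / "mu_a.csv")
    props.mu_s_reduced.to_csv(out / "mu_s_reduced.csv")
    predefined.to_csv(out / "predefined_mus.csv")
    n_fixed = int(np.sum(props.mode == "fixed_mus"))
    report = {
        **config.provenance(),
        "scatterer_concentration": float(concentration),
        "anchor_nm": anchor,
        "mus_reduced_at_anchor": float(sol.mu_s_reduced),
        "n_wavelengths": int(props.wavelengths.size),
        "n_fixed_mus": n_fixed,
        "mode": [str(m) for m in props.mode],
        "lut": {k: lut.meta.get(k) for k in ("seed", "n_photons",
                                             "refine_rel_se", "max_photons")},
    }
    (out / "inversion_report.json").write_text(json.dumps(report, indent=2))
    props.extras["predefined_mus"] = predefined
    props.extras["scatterer_concentration"] = concentration
    return props, report


def run_recipe(config: PipelineConfig, target: OpticalProperties,
               basis: PigmentBasis | None = None,
               baseline: Spectrum | None = None):
    """Two-stage pigment fit against the target absorption spectrum.

    Full-basis bounded least squares, pruning to the significantly
    contributing pigments, then a refit on that subset (mirroring how a
    practical recipe keeps only pigments worth weighing in).
    """
    if basis is None:
        config.validate_paths(("basis_dir",))
        basis = PigmentBasis.from_directory(config["paths"]["basis_dir"])
    fit = config["fit"]
    grid = basis.wavelengths
    lo, hi = fit["grid_lo_nm"], fit["grid_hi_nm"]
    grid = grid[(grid >= lo) & (grid <= hi)]
    basis_g = basis.resample(grid)
    target_mu_a = target.mu_a.resample(grid)
    if baseline is None:
        baseline = Spectrum(grid, np.zeros(grid.size), kind="mu_a",
                            name="zero_baseline")
    else:
        baseline = baseline.resample(grid)

    full = fit_recipe(basis_g, target_mu_a, baseline,
                      n_starts=fit["n_starts"], seed=fit["seed"])
    kept = select_significant(full, basis_g, fit["significance_threshold"])
    sub = fit_recipe(basis_g.subset(kept), target_mu_a, baseline,
                     n_starts=fit["n_starts"], seed=fit["seed"])
    mre = mean_relative_error(sub.fitted_mu_a, target_mu_a)

    out = config.output_dir()
    sub.to_json(out / "recipe.json")
    sub.fitted_mu_a.to_csv(out / "fitted_mu_a.csv")
    target_mu_a.to_csv(out / "target_mu_a.csv")
    report = {
        **config.provenance(),
        "n_pigments_full": len(basis_g),
        "significant_indices": list(kept),
        "significant_names": [basis_g.names[i] for i in kept],
        "chi_squared_full": full.chi_squared,
        "chi_squared_subset": sub.chi_squared,
        "mean_relative_error_pct": mre,
    }
    (out / "recipe_report.json").write_text(json.dumps(report, indent=2))
    return sub, kept, report


def run_compare(config: PipelineConfig, fitted_mu_a: Spectrum,
                predefined_mus: Spectrum, target_R: Spectrum,
                lut: LUT | None = None,
                oi: ObserverIlluminant | None = None) -> dict:
    """Predict phantom reflectance and report the colour difference.

    The phantom's R(lambda) is read from the LUT forward model at the
    (fitted mu_a, predefined mu_s') pair per wavelength; wavelengths
    whose coefficients fall outside the LUT hull are flagged and
    excluded from the CIEDE2000 integration with a warning.
    """
    lut = get_or_build_lut(config, lut)
    wl = target_R.wavelengths
    mu_a = fitted_mu_a(wl)
    musr = predefined_mus(wl)
    pred = np.empty(wl.size)
    inside = np.ones(wl.size, dtype=bool)
    for k in range(wl.size):
        try:
            pred[k], _ = lut_forward(lut, float(mu_a[k]), float(musr[k]),
                                     value_space="log")
        except OutOfRangeError:
            inside[k] = False
            pred[k] = np.nan
    if not inside.all():
        log.warning("%d wavelengths outside the LUT hull excluded from the "
                    "colour comparison", int((~inside).sum()))
    pred_spec = Spectrum(wl[inside], np.clip(pred[inside], 0.0, 1.0),
                         kind="reflectance", name="R_phantom_predicted")
    target_spec = Spectrum(wl[inside], target_R.values[inside],
                           kind="reflectance", name="R_target")
    de = delta_e_between_spectra(pred_spec, target_spec, oi)

    out = config.output_dir()
    pred_spec.to_csv(out / "phantom_reflectance_predicted.csv")
    target_spec.to_csv(out / "target_reflectance.csv")
    report = {
        **config.provenance(),
        "delta_e_2000": float(de),
        "n_wavelengths_compared": int(inside.sum()),
        "n_excluded_out_of_hull": int((~inside).sum()),
    }
    (out / "compare_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_all(config: PipelineConfig, lut: LUT | None = None,
            basis: PigmentBasis | None = None,
            baseline: Spectrum | None = None,
            scatterer: ScattererModel | None = None) -> dict:
    """Inversion -> recipe -> comparison, sharing one LUT."""
    lut = get_or_build_lut(config, lut)
    props, inv_report = run_inversion(config, lut=lut, scatterer=scatterer)
    recipe, kept, rec_report = run_recipe(config, props, basis=basis,
                                          baseline=baseline)
    target_R = Spectrum.from_csv(config["paths"]["r_spectrum"],
                                 kind="reflectance")
    fit = config["fit"]
    lo, hi = fit["grid_lo_nm"], fit["grid_hi_nm"]
    target_R_vis = target_R.restrict(lo, hi)
    cmp_report = run_compare(config, recipe.fitted_mu_a,
                             props.extras["predefined_mus"], target_R_vis,
                             lut=lut)
    report = {"inversion": inv_report, "recipe": rec_report,
              "comparison": cmp_report}
    (config.output_dir() / "report.json").write_text(
        json.dumps(report, indent=2))
    return report
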