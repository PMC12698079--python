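"""Typed wavelength/value series and their CSV representation.

A :class:`Spectrum` is the universal I/O unit of the package: measured
reflectance and transmittance, absorption and reduced-scattering
coefficients, pigment specific absorption and illuminant power
distributions are all carried on a strictly increasing wavelength grid
in nanometres.  Spectra are immutable; arithmetic helpers return new
instances.

CSV layout is two columns with the header ``wavelength_nm,value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GridError, OutOfRangeError

#: Recognised spectrum kinds.  Fraction kinds are bounded to [0, 1];
#: coefficient kinds must be non-negative.
KINDS = (
    "reflectance",
    "transmittance",
    "mu_a",
    "mu_s_reduced",
    "specific_absorption",
    "illuminant_spd",
    "generic",
)
_FRACTION_KINDS = {"reflectance", "transmittance"}
_NONNEG_KINDS = {"mu_a", "mu_s_reduced", "specific_absorption", "illuminant_spd"}


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-resolved quantity on a strictly increasing grid.

    Parameters
    ----------
    wavelengths : array-like
        Wavelengths in nm, strictly increasing, no duplicates.
    values : array-like
        Values, same length as ``wavelengths``.
    kind : str
        One of :data:`KINDS`; controls range validation.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "generic"
    name: str = field(default="", compare=False)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise GridError("wavelengths and values must be 1-D of equal length")
        if wl.size == 0:
            raise GridError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise GridError("wavelengths must be strictly increasing (no duplicates)")
        if self.kind not in KINDS:
            raise GridError(f"unknown spectrum kind {self.kind!r}")
        if self.kind in _FRACTION_KINDS and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise GridError(f"{self.kind} values must lie in [0, 1]")
        if self.kind in _NONNEG_KINDS and vals.min() < -1e-12:
            raise GridError(f"{self.kind} values must be non-negative")
        wl.setflags(write=False)
        vals.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size

    # -- evaluation ---------------------------------------------------

    def __call__(self, wavelength) -> np.ndarray | float:
        """Linear interpolation; extrapolation is an error."""
        w = np.asarray(wavelength, dtype=float)
        if np.any(w < self.wavelengths[0]) or np.any(w > self.wavelengths[-1]):
            raise OutOfRangeError(
                f"wavelength query outside [{self.wavelengths[0]}, "
                f"{self.wavelengths[-1]}] nm",
                axis="wavelength",
            )
        out = np.interp(w, self.wavelengths, self.values)
        return float(out) if np.isscalar(wavelength) else out

    def resample(self, grid) -> "Spectrum":
        """Interpolate onto a new grid (must lie inside the current one)."""
        grid = np.asarray(grid, dtype=float)
        return Spectrum(grid, self(grid), kind=self.kind, name=self.name)

    def with_values(self, values, kind: str | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths, values, kind=kind or self.kind, name=self.name)

    def scaled(self, factor: float) -> "Spectrum":
        return self.with_values(self.values * factor)

    def restrict(self, lo: float, hi: float) -> "Spectrum":
        """Keep only samples with lo <= wavelength <= hi."""
        m = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not m.any():
            raise OutOfRangeError(f"no samples in [{lo}, {hi}] nm", axis="wavelength")
        return Spectrum(self.wavelengths[m], self.values[m], kind=self.kind, name=self.name)

    # -- I/O ----------------------------------------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "generic", name: str = "") -> "Spectrum":
        df = pd.read_csv(path)
        cols = [c.strip() for c in df.columns]
        if cols[:2] != ["wavelength_nm", "value"]:
            raise GridError(
                f"{path}: expected header 'wavelength_nm,value', got {cols[:2]}"
            )
        return cls(
            df["wavelength_nm"].to_numpy(float),
            df["value"].to_numpy(float),
            kind=kind,
            name=name or Path(path).stem,
        )


def common_grid(*spectra: Spectrum, step: float | None = None) -> np.ndarray:
    """Overlapping wavelength grid of several spectra.

    With ``step`` given, a uniform grid over the overlap; otherwise the
    union of sample points restricted to the overlap.
    """
    lo = max(s.wavelengths[0] for s in spectra)
    hi = min(s.wavelengths[-1] for s in spectra)
    if lo > hi:
        raise OutOfRangeError("spectra do not overlap", axis="wavelength")
    if step is not None:
        return np.arange(lo, hi + step / 2, step)
    pts = np.unique(np.concatenate([s.wavelengths for s in spectra]))
    return pts[(pts >= lo) & (pts <= hi)]


def default_analysis_grid(lo: float = 400.0, hi: float = 1000.0, step: float = 5.0) -> np.ndarray:
    """The package's default 5 nm analysis grid, 400-1000 nm."""
    return np.arange(lo, hi + step / 2, step)
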