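"""Reflectance-spectrum colorimetry: XYZ, CIELAB and CIEDE2000.

Spectra are reduced to tristimulus values by rectangular quadrature of
reflectance x illuminant x colour-matching functions, normalised so the
perfect diffuser has Y = 100, then converted to CIELAB and compared
with the full CIEDE2000 formula (lightness, chroma and hue terms, the
G chroma correction and the blue-region rotation term).

The bundled observer/illuminant tables are *synthetic*: smooth analytic
stand-ins shaped like a wide-field (10 degree) observer and a daylight
(D65-like) source, shipped because official CIE 170-2 / D65 tables
cannot be redistributed here.  Every numerical guarantee of this module
(white-point identity, linearity, the CIEDE2000 verification pairs) is
independent of the table values; for publication-grade colour numbers
load official CIE tables via :meth:`ObserverIlluminant.from_csv`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, OutOfRangeError
from .spectra import Spectrum

__all__ = [
    "ObserverIlluminant", "LabColor", "spectrum_to_xyz", "xyz_to_lab",
    "delta_e_2000", "delta_e_between_spectra",
]


@dataclass(frozen=True)
class LabColor:
    """CIELAB coordinates."""

    L_star: float
    a_star: float
    b_star: float

    def __iter__(self):
        return iter((self.L_star, self.a_star, self.b_star))


@dataclass(frozen=True)
class ObserverIlluminant:
    """Colour-matching functions plus an illuminant power distribution."""

    cmf_x: Spectrum
    cmf_y: Spectrum
    cmf_z: Spectrum
    illuminant: Spectrum
    name: str = "synthetic-10deg/d65-like"

    @classmethod
    def default(cls) -> "ObserverIlluminant":
        """The bundled synthetic observer/illuminant pair."""
        pkg = resources.files("fingerphantom") / "data"
        obs = pd.read_csv(pkg / "observer_10deg_synthetic.csv")
        wl = obs["wavelength_nm"].to_numpy(float)
        ill = Spectrum.from_csv(pkg / "illuminant_d65_synthetic.csv",
                                kind="illuminant_spd", name="d65_synthetic")
        return cls(
            Spectrum(wl, obs["xbar"].to_numpy(float), name="xbar"),
            Spectrum(wl, obs["ybar"].to_numpy(float), name="ybar"),
            Spectrum(wl, obs["zbar"].to_numpy(float), name="zbar"),
            ill)

    @classmethod
    def from_csv(cls, observer_path, illuminant_path,
                 name: str = "user") -> "ObserverIlluminant":
        """Load user-supplied tables (e.g. official CIE data).

        The observer CSV needs columns wavelength_nm, xbar, ybar, zbar;
        the illuminant CSV the standard wavelength_nm, value layout.
        """
        obs = pd.read_csv(observer_path)
        wl = obs["wavelength_nm"].to_numpy(float)
        return cls(
            Spectrum(wl, obs["xbar"].to_numpy(float), name="xbar"),
            Spectrum(wl, obs["ybar"].to_numpy(float), name="ybar"),
            Spectrum(wl, obs["zbar"].to_numpy(float), name="zbar"),
            Spectrum.from_csv(illuminant_path, kind="illuminant_spd"),
            name=name)

    @property
    def white_point(self) -> tuple[float, float, float]:
        """XYZ of the perfect diffuser (Y normalised to 100)."""
        wl = self.cmf_y.wavelengths
        ones = Spectrum(wl, np.ones(wl.size), kind="reflectance")
        return spectrum_to_xyz(ones, self)


def _quadrature_grid(reflectance: Spectrum, oi: ObserverIlluminant):
    lo = max(reflectance.wavelengths[0], oi.cmf_y.wavelengths[0],
             oi.illuminant.wavelengths[0])
    hi = min(reflectance.wavelengths[-1], oi.cmf_y.wavelengths[-1],
             oi.illuminant.wavelengths[-1])
    if lo >= hi:
        raise OutOfRangeError("reflectance and observer tables do not overlap",
                              axis="wavelength")
    wl = reflectance.wavelengths
    wl = wl[(wl >= lo) & (wl <= hi)]
    if wl.size < 2:
        raise OutOfRangeError("fewer than 2 samples in the overlap",
                              axis="wavelength")
    return wl


def spectrum_to_xyz(reflectance: Spectrum, oi: ObserverIlluminant
                    ) -> tuple[float, float, float]:
    """Tristimulus XYZ of a reflectance spectrum under ``oi``.

    Rectangular quadrature on the reflectance's native grid restricted
    to the table overlap, scaled by k = 100 / sum(S ybar dlambda) so
    the perfect diffuser maps to Y = 100 exactly.
    """
    if reflectance.kind not in ("reflectance", "generic"):
        raise InvalidParameterError(
            f"expected a reflectance spectrum, got kind {reflectance.kind!r}")
    wl = _quadrature_grid(reflectance, oi)
    dl = np.gradient(wl)
    R = reflectance(wl)
    S = oi.illuminant(wl)
    k = 100.0 / float(np.sum(S * oi.cmf_y(wl) * dl))
    X = k * float(np.sum(R * S * oi.cmf_x(wl) * dl))
    Y = k * float(np.sum(R * S * oi.cmf_y(wl) * dl))
    Z = k * float(np.sum(R * S * oi.cmf_z(wl) * dl))
    return X, Y, Z


def _f_lab(t: float) -> float:
    delta = 6.0 / 29.0
    if t > delta ** 3:
        return t ** (1.0 / 3.0)
    return t / (3.0 * delta * delta) + 4.0 / 29.0


def xyz_to_lab(xyz, oi: ObserverIlluminant) -> LabColor:
    """CIELAB from XYZ relative to the observer/illuminant white point."""
    X, Y, Z = (float(v) for v in xyz)
    if min(X, Y, Z) < 0:
        raise InvalidParameterError("XYZ components must be non-negative")
    Xn, Yn, Zn = oi.white_point
    fx, fy, fz = _f_lab(X / Xn), _f_lab(Y / Yn), _f_lab(Z / Zn)
    return LabColor(116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz))


def delta_e_2000(ref: LabColor, sample: LabColor,
                 kL: float = 1.0, kC: float = 1.0, kH: float = 1.0) -> float:
    """CIEDE2000 colour difference between two CIELAB colours."""
    L1, a1, b1 = ref
    L2, a2, b2 = sample
    for v in (L1, a1, b1, L2, a2, b2):
        if not math.isfinite(v):
            raise InvalidParameterError("Lab inputs must be finite")

    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    c7 = Cbar ** 7
    G = 0.5 * (1.0 - math.sqrt(c7 / (c7 + 25.0 ** 7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = math.hypot(a1p, b1)
    C2p = math.hypot(a2p, b2)

    def hue(ap, b):
        if ap == 0.0 and b == 0.0:
            return 0.0
        h = math.degrees(math.atan2(b, ap))
        return h + 360.0 if h < 0.0 else h

    h1p = hue(a1p, b1)
    h2p = hue(a2p, b2)

    dLp = L2 - L1
    dCp = C2p - C1p
    if C1p * C2p == 0.0:
        dhp = 0.0
    else:
        dhp = h2p - h1p
        if dhp > 180.0:
            dhp -= 360.0
        elif dhp < -180.0:
            dhp += 360.0
    dHp = 2.0 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    if C1p * C2p == 0.0:
        hbp = h1p + h2p
    else:
        hsum = h1p + h2p
        if abs(h1p - h2p) <= 180.0:
            hbp = 0.5 * hsum
        elif hsum < 360.0:
            hbp = 0.5 * (hsum + 360.0)
        else:
            hbp = 0.5 * (hsum - 360.0)

    T = (1.0 - 0.17 * math.cos(math.radians(hbp - 30.0))
         + 0.24 * math.cos(math.radians(2.0 * hbp))
         + 0.32 * math.cos(math.radians(3.0 * hbp + 6.0))
         - 0.20 * math.cos(math.radians(4.0 * hbp - 63.0)))
    dtheta = 30.0 * math.exp(-(((hbp - 275.0) / 25.0) ** 2))
    cb7 = Cbp ** 7
    RC = 2.0 * math.sqrt(cb7 / (cb7 + 25.0 ** 7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / math.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -math.sin(math.radians(2.0 * dtheta)) * RC

    tL = dLp / (kL * SL)
    tC = dCp / (kC * SC)
    tH = dHp / (kH * SH)
    return math.sqrt(tL * tL + tC * tC + tH * tH + RT * tC * tH)


def delta_e_between_spectra(r1: Spectrum, r2: Spectrum,
                            oi: ObserverIlluminant | None = None) -> float:
    """CIEDE2000 between two reflectance spectra under one observer."""
    oi = oi or ObserverIlluminant.default()
    lab1 = xyz_to_lab(spectrum_to_xyz(r1, oi), oi)
    lab2 = xyz_to_lab(spectrum_to_xyz(r2, oi), oi)
    return delta_e_2000(lab1, lab2)
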