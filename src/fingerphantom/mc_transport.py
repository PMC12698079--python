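"""Photon-packet Monte-Carlo forward model with integrating-sphere detection.

Solves the radiative transport equation for homogeneous slab and
finite-cylinder samples with refractive-index-mismatched boundaries,
Henyey-Greenstein scattering and weighted-packet variance reduction.
The finger is modelled as a homogeneous cylinder illuminated
perpendicular to its axis; detection is position-only acceptance within
a circular sample-port disc on the reflectance or transmittance side.

Units: lengths mm, coefficients mm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .errors import GeometryError, InvalidParameterError

__all__ = [
    "OpticalPoint",
    "Geometry",
    "BeamConfig",
    "SphereConfig",
    "MCResult",
    "sample_hg_deflection",
    "fresnel_unpolarized",
    "next_boundary_distance",
    "classify_exit",
    "simulate_rt",
    "DEFAULT_G",
]

#: Scattering anisotropy assumed throughout (Henyey-Greenstein mean cosine).
DEFAULT_G = 0.75


@dataclass(frozen=True)
class OpticalPoint:
    """Single-wavelength optical properties of the medium.

    ``mu_a`` and ``mu_s`` in mm^-1; ``g`` is the Henyey-Greenstein
    anisotropy; ``n_in``/``n_out`` the sample/surround refractive
    indices.
    """

    mu_a: float
    mu_s: float
    g: float = DEFAULT_G
    n_in: float = 1.4
    n_out: float = 1.0

    def __post_init__(self):
        if self.mu_a < 0 or self.mu_s < 0:
            raise InvalidParameterError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise InvalidParameterError("anisotropy g must lie in (-1, 1)")
        if self.n_in < 1.0 or self.n_out < 1.0:
            raise InvalidParameterError("refractive indices must be >= 1")

    @property
    def mu_s_reduced(self) -> float:
        """Reduced scattering coefficient mu_s' = mu_s (1 - g)."""
        return self.mu_s * (1.0 - self.g)

    @classmethod
    def from_reduced(cls, mu_a: float, mu_s_reduced: float, g: float = DEFAULT_G,
                     n_in: float = 1.4, n_out: float = 1.0) -> "OpticalPoint":
        """Build from mu_s' via mu_s = mu_s' / (1 - g)."""
        if mu_s_reduced < 0:
            raise InvalidParameterError("mu_s_reduced must be non-negative")
        return cls(mu_a, mu_s_reduced / (1.0 - g), g=g, n_in=n_in, n_out=n_out)


@dataclass(frozen=True)
class Geometry:
    """Sample geometry: an axial slab or a barrel-illuminated cylinder.

    ``thickness_or_diameter`` is the slab thickness along the beam or
    the cylinder diameter; ``lateral_extent`` the slab diameter or the
    cylinder length.
    """

    kind: str
    thickness_or_diameter: float
    lateral_extent: float

    def __post_init__(self):
        if self.kind not in ("slab", "cylinder"):
            raise GeometryError(f"unknown geometry kind {self.kind!r}")
        if self.thickness_or_diameter <= 0 or self.lateral_extent <= 0:
            raise GeometryError("geometry dimensions must be positive")

    @classmethod
    def slab(cls, thickness: float, diameter: float = 35.0) -> "Geometry":
        return cls("slab", thickness, diameter)

    @classmethod
    def cylinder(cls, diameter: float = 13.8, length: float = 60.0) -> "Geometry":
        """Finger-like cylinder; default diameter is the measured finger
        thickness, length is large compared to the transport length."""
        return cls("cylinder", diameter, length)

    @property
    def _kind_tag(self) -> int:
        return _kernel.SLAB if self.kind == "slab" else _kernel.CYLINDER

    @property
    def _dims(self) -> tuple[float, float]:
        if self.kind == "slab":
            return self.thickness_or_diameter, self.lateral_extent / 2.0
        return self.thickness_or_diameter / 2.0, self.lateral_extent / 2.0

    def contains(self, position) -> bool:
        x, y, z = (float(v) for v in position)
        d1, d2 = self._dims
        if self.kind == "slab":
            return 0.0 < z < d1 and math.hypot(x, y) < d2
        return x * x + z * z < d1 * d1 and abs(y) < d2


@dataclass(frozen=True)
class BeamConfig:
    """Illumination: flat-top disc of ``beam_diameter`` mm (0 = pencil),
    normally incident on the slab face / perpendicular to the cylinder
    axis, centred on the origin."""

    beam_diameter: float = 5.0
    profile: str = "flat_top"

    def __post_init__(self):
        if self.beam_diameter < 0:
            raise InvalidParameterError("beam_diameter must be >= 0")
        if self.profile not in ("flat_top", "pencil"):
            raise InvalidParameterError(f"unknown beam profile {self.profile!r}")

    @property
    def radius(self) -> float:
        return 0.0 if self.profile == "pencil" else self.beam_diameter / 2.0

    @classmethod
    def pencil(cls) -> "BeamConfig":
        return cls(0.0, "pencil")


@dataclass(frozen=True)
class SphereConfig:
    """Integrating-sphere acceptance model.

    A packet is detected when its exit point lies inside the circular
    sample-port disc centred on the beam axis (on either the reflectance
    or the transmittance side), regardless of exit angle.  With
    ``count_specular`` false the packet specularly reflected at entry is
    lost through the entrance port instead of being counted.
    """

    sphere_inner_diameter: float = 150.0
    entrance_port_diameter: float = 10.0
    sample_port_diameter: float = 25.0
    count_specular: bool = False

    def __post_init__(self):
        for d in (self.sphere_inner_diameter, self.entrance_port_diameter,
                  self.sample_port_diameter):
            if d <= 0:
                raise InvalidParameterError("sphere diameters must be positive")
        if max(self.entrance_port_diameter, self.sample_port_diameter) >= \
                self.sphere_inner_diameter:
            raise InvalidParameterError("port diameters must be smaller than the sphere")


@dataclass(frozen=True)
class MCResult:
    """Detected fractions of one Monte-Carlo run.

    ``R`` + ``T`` + ``A`` + ``L`` = 1 exactly: absorbed weight is the
    remainder of launched weight over all escape channels (Russian-
    roulette residuals are counted as absorbed).
    """

    R: float
    T: float
    A: float
    L: float
    se_R: float
    se_T: float
    n_photons: int
    seed: int
    meta: dict = field(default_factory=dict, compare=False)


def sample_hg_deflection(g: float, u) -> float | np.ndarray:
    """Deflection cosine of Henyey-Greenstein scattering.

    Inverse-CDF sampling: cos(theta) = (1 + g^2 - ((1-g^2)/(1-g+2gu))^2)
    / (2g); for g = 0 this degenerates to the isotropic 2u - 1.
    """
    if not -1.0 < g < 1.0:
        raise InvalidParameterError("|g| must be < 1")
    if np.isscalar(u):
        return _kernel.hg_cos(g, float(u))
    return np.array([_kernel.hg_cos(g, float(v)) for v in np.asarray(u).ravel()])


def fresnel_unpolarized(n_from: float, n_to: float, cos_incident: float
                        ) -> tuple[float, float, bool]:
    """Unpolarized Fresnel reflection probability at a planar interface.

    Returns ``(reflectance, cos_refracted, tir)``; beyond the critical
    angle the reflectance is 1 and ``tir`` is set.
    """
    if n_from < 1.0 or n_to < 1.0:
        raise InvalidParameterError("refractive indices must be >= 1")
    if not 0.0 < cos_incident <= 1.0:
        raise InvalidParameterError("cos_incident must lie in (0, 1]")
    r, ct, tir = _kernel.fresnel(float(n_from), float(n_to), float(cos_incident))
    return r, ct, tir


def next_boundary_distance(position, direction, geometry: Geometry) -> float:
    """Distance along ``direction`` to the first boundary of ``geometry``."""
    x, y, z = (float(v) for v in position)
    ux, uy, uz = (float(v) for v in direction)
    nrm = math.sqrt(ux * ux + uy * uy + uz * uz)
    if abs(nrm - 1.0) > 1e-6:
        raise GeometryError("direction must be a unit vector")
    if not geometry.contains((x, y, z)):
        raise GeometryError("position must lie strictly inside the geometry")
    d1, d2 = geometry._dims
    dist, face = _kernel.boundary_distance(geometry._kind_tag, d1, d2,
                                           x, y, z, ux, uy, uz)
    if face < 0:
        raise GeometryError("no boundary along this ray (degenerate direction)")
    return dist


def classify_exit(exit_position, exit_direction, geometry: Geometry,
                  sphere: SphereConfig, measurement_side: str = "both",
                  unscattered: bool = False) -> str:
    """Channel of an exiting packet: reflectance, transmittance or lost.

    Acceptance is position-only: inside the sample-port disc on the
    respective side.  An unscattered specularly reflected packet is lost
    when ``count_specular`` is false.
    """
    x, y, z = (float(v) for v in exit_position)
    d1, d2 = geometry._dims
    if geometry.kind == "slab":
        if abs(z) < 1e-9:
            face = 0
        elif abs(z - d1) < 1e-9:
            face = 1
        else:
            face = 2
    else:
        face = 1 if abs(abs(y) - d2) < 1e-9 else 0
    ch = _kernel.classify_exit(geometry._kind_tag, face, x, y, z,
                               sphere.sample_port_diameter / 2.0)
    name = {_kernel.CH_REFLECT: "reflectance",
            _kernel.CH_TRANSMIT: "transmittance",
            _kernel.CH_LOST: "lost"}[ch]
    if name == "reflectance" and unscattered and not sphere.count_specular:
        return "lost"
    if measurement_side in ("reflectance", "transmittance") and \
            name not in (measurement_side, "lost"):
        return "lost"
    return name


def simulate_rt(optics: OpticalPoint, geometry: Geometry,
                beam: BeamConfig | None = None,
                sphere: SphereConfig | None = None,
                n_photons: int = 100_000, seed: int = 0,
                roulette_threshold: float = 1e-4,
                roulette_survival: float = 0.1) -> MCResult:
    """Run the forward Monte-Carlo model and return detected fractions.

    Identical ``(seed, inputs)`` reproduce bit-identical output; the
    standard errors are estimated from per-photon channel weights.
    """
    if n_photons < 1:
        raise InvalidParameterError("n_photons must be >= 1")
    beam = beam or BeamConfig()
    sphere = sphere or SphereConfig()
    d1, d2 = geometry._dims
    sums = _kernel.run_photons(
        geometry._kind_tag, d1, d2,
        float(optics.mu_a), float(optics.mu_s), float(optics.g),
        float(optics.n_in), float(optics.n_out),
        beam.radius, sphere.sample_port_diameter / 2.0,
        sphere.count_specular,
        int(n_photons), np.uint64(seed),
        float(roulette_threshold), float(roulette_survival))
    n = float(n_photons)
    R = sums[0] / n
    T = sums[1] / n
    L = sums[2] / n
    A = 1.0 - R - T - L  # exact remainder: absorbed weight
    if -1e-13 < A < 0.0:  # rounding of the per-channel normalisations
        A = 0.0
    se_R = math.sqrt(max(0.0, sums[3] / n - R * R) / n)
    se_T = math.sqrt(max(0.0, sums[4] / n - T * T) / n)
    return MCResult(R=R, T=T, A=A, L=L, se_R=se_R, se_T=se_T,
                    n_photons=int(n_photons), seed=int(seed))
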