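# Methods

This note documents the models, numerical choices and limitations of
`fingerphantom`. It is the package's own account of its science; every
number quoted here is computed by the test suite or by
`scripts/acceptance.py`, not asserted from elsewhere.

## Problem

Designing a tissue-realistic optical phantom of a human finger requires
three computational pieces:

1. **An inverse model for the finger.** Integrating-sphere reflectance
   R(λ) and transmittance T(λ) of a finger-thick sample must be turned
   into the absorption coefficient μa(λ) and reduced scattering
   coefficient μs′(λ). The finger is modelled as a homogeneous cylinder
   (diameter 13.8 mm by default) illuminated perpendicular to its axis,
   so a slab model does not apply and the forward model must be solved
   by Monte-Carlo photon transport.
2. **A recipe for the phantom material.** Given a target μa(λ) and a
   basis of pigment specific-absorption spectra, find non-negative
   pigment concentrations whose mixture (plus the matrix/scatterer
   baseline) reproduces the target.
3. **A figure of merit.** The predicted phantom reflectance is compared
   to the target reflectance with the CIEDE2000 colour difference.

## Photon transport (`mc_transport`)

Weighted photon packets solve the radiative transport equation:

* step length s = −ln(u)/(μa+μs); at each interaction the packet keeps
  the albedo fraction μs/(μa+μs) of its weight and scatters through a
  Henyey–Greenstein deflection with anisotropy g (default 0.75); the
  azimuth is uniform.
* boundaries are refractive-index-mismatched (sample n≈1.4 in air);
  the unpolarized Fresnel probability decides stochastically between
  specular reflection (total internal reflection is certain reflection)
  and refraction out of the sample.
* Russian roulette below weight 1e−4 with survival probability 0.1
  (survivors are re-weighted ×10).
* geometries: a finite slab (beam along the axis, lateral barrel) and a
  finite cylinder (axis ⟂ beam, default length 60 mm ≫ transport
  length; packets crossing the end caps are lost). Both reduce to the
  same ray–cylinder intersection code.
* detection is position-only: a packet is detected when its exit point
  lies inside a circular sample-port disc (default diameter 25 mm)
  centred on the beam axis, on the reflectance or the transmittance
  side. The packet specularly reflected at entry is assigned to the
  lost channel by default (it would retrace into the entrance port);
  `count_specular=true` counts it as reflectance instead.

**Energy bookkeeping.** The absorbed fraction A is the exact remainder
of launched weight over the escape channels, so R+T+A+L ≡ 1 to better
than 1e−12 on every run; roulette residuals are counted as absorbed
(they are ≤1e−3 per packet by construction). Standard errors of R and T
come from per-packet channel weights.

**Reproducibility.** Each packet's random stream is a splitmix64
generator keyed by (run seed, packet index), so results are bit-stable
and independent of execution order. All sub-seeds (LUT nodes,
wavelengths, batches) derive from one master seed through the same
mixing function.

## LUT inversion (`sphere_lut`)

The forward model is tabulated on log-spaced grids, by default 16×16
over μa ∈ [1e−3, 2] mm⁻¹ and μs′ ∈ [0.2, 6] mm⁻¹ — covering the
finger-regime coefficients with margin. Node photon budgets are
adaptive: each node starts at 25 000 packets and is refined in equal
batches until the relative standard errors of R and T drop below 10% or
400 000 packets are spent. This concentrates photons where T is tiny —
the high-absorption nodes — which are exactly the cheap ones to
simulate, and keeps a full LUT build in the minutes range on one CPU.

**Interpolation.** Queries are bilinear in (log μa, log μs′). Two value
spaces are offered: `linear` (the default; the cell midpoint is the
arithmetic mean of the four nodes) and `log`, which interpolates the
logarithms of R and T. The inverters use the log value space: T decays
near-exponentially with absorption, spanning an order of magnitude or
more per cell at the dark corner of the grid, and linear-value
interpolation there biases recovered μa by several percent, while
log-value interpolation keeps the cell-midpoint bias far below the
Monte-Carlo noise.

**Two-channel inversion** minimises the sum of squared relative
residuals of (R, T) — an exhaustive scan on a 4× subdivided grid (ties
broken toward smaller μa by scan order) followed by Nelder–Mead in log
coefficients, clipped to the hull. Solutions pinned to the hull edge
carry a boundary flag; residuals above 0.25 raise an error, as do
infeasible inputs (R+T ≥ 1).

**Fixed-μs′ branch.** Where T falls below the floor (default 5e−4, the
"negligible transmittance" regime of a finger below 600 nm), only μa is
recovered: R(μa; μs′) is monotone decreasing in μa, so Brent root
finding on the interpolated forward model solves R = R_meas. The
predefined μs′(λ) comes from the scatterer model scaled so that its
μs′ matches the finger's at the 700 nm anchor (exact by construction:
concentration = target/model(700)). If the scatterer's spectral slope
differs from the tissue's, the predefined μs′ is wrong away from the
anchor and the recovered μa shifts systematically in one direction —
the tests assert this sign consistency rather than pretending the
branch is unbiased.

**Slab-series stitching.** For slab phantoms measured at several
thicknesses, the per-wavelength estimate is taken from the thickest
slab whose T lies in a conditioning window (default 0.05–0.8; thick
slabs give the best-conditioned inversion, but only while T remains
measurable). When no slab qualifies, the slab with T closest to the
window is used and flagged. The window and the prefer-thickest rule are
this package's interpretation of "optimal R and T" stitching; both are
config keys.

## Recipe fitting (`pigment_recipe`)

Specific absorption is extracted from preconcentration measurements as
ε(λ) = (μa,sample − μa,control)/c, clipping negative values to zero
with a warning. Recipe fitting minimises χ² = Σλ (baseline + Σi ci
εi(λ) − target(λ))² subject to 0 ≤ ci ≤ ub, restarted from 30 seeded
uniform-random initial points with the lowest-χ² winner kept. The
problem is a bounded convex quadratic, so all restarts must coincide —
the suite checks the multi-start optimum against a direct NNLS solve
(≤1e−8 relative) and that the restart spread is below 1e−6 of the
signal energy. χ² is unweighted by default (a per-wavelength weight
vector is accepted); upper bounds default to 10× the largest extraction
concentration recorded in the basis, falling back to 10× the
single-pigment concentration that would explain the whole target.

Significance pruning keeps pigment i iff max over λ of its share
ci εi(λ) / (fitted − baseline)(λ) reaches a threshold (default 1%);
the pipeline then refits on the kept subset, mirroring how a practical
recipe keeps only pigments worth weighing in.

## Colorimetry (`colorimetry`)

XYZ is a rectangular-quadrature reduction on the reflectance spectrum's
native grid restricted to the table overlap, normalised so the perfect
diffuser has Y = 100; CIELAB uses the standard cube-root transform with
the linear segment below (6/29)³; CIEDE2000 implements the full formula
(G chroma correction, hue means, and the blue-region rotation term).
The implementation reproduces the standard published verification pairs
to 1e−4 and matches scikit-image's independent implementation to 1e−9
on random Lab pairs.

The bundled observer/illuminant tables are **synthetic**: analytic
Gaussian-sum stand-ins with the shape of a wide-field (10°) observer
and a smooth daylight-like source, shipped because official CIE tables
cannot be redistributed here. All guarantees above are independent of
the table values; for publication-grade colour coordinates load
official CIE 170-2 / D65 tables through
`ObserverIlluminant.from_csv`, which also serves as the switch to any
other observer (e.g. the 1964 10°) for sensitivity checks.

## Synthetic study conditions (`synthetic_data`)

The generators emulate the features of the real measurement campaign
that the pipeline's behaviour depends on:

* **Finger truth:** μs′(λ) = a(λ/700)^(−b) with a ∈ [1, 2] mm⁻¹ and
  b ∈ [0.5, 1.5]; μa is a smooth baseline plus 2–3 Gaussian bands
  (centres 430–565 nm, widths 15–35 nm, amplitudes 0.5–1.2 mm⁻¹) and a
  logistic shelf below ~600 nm, capped at 1.8 mm⁻¹ (a finger-realistic
  ceiling that also keeps the truth inside the default inversion grid).
  The construction makes T through the 13.8 mm cylinder collapse below
  600 nm — verified by forward simulation — so the fixed-μs′ branch is
  genuinely exercised.
* **Scatterer:** a ZrO2-like power law with slope exponent 0.6,
  deliberately shallower than the tissue-like truth so the anchored
  predefined μs′ deviates at short wavelengths, as in reality.
* **Pigments:** 15 spectra of 1–3 Gaussian bands each; the target is
  composed from exactly 5 of them with known concentrations, so
  recovery and pruning have an exact ground truth.
* **Noise:** multiplicative 1% plus an absolute floor of 1e−4, typical
  integrating-sphere repeatability.

What the generators do **not** emulate: layered skin anatomy,
chromophore libraries with literature extinction spectra, instrument
sphere-error corrections, surface roughness/gloss, or spatial
heterogeneity. Passing tests therefore demonstrate that the inverse
pipeline recovers the truth of a homogeneous cylinder under realistic
noise — not that a real finger is such a cylinder.

## Problem sizes and tolerances

The suite and the acceptance script use sizes chosen to make Monte-
Carlo noise comfortably smaller than the tolerances they check on a
single CPU: 16×16 LUT with 25k–400k adaptive packets per node, 10⁶
forward packets for the nine-point round trip (tolerance 5% on both
coefficients), 10⁵ packets per wavelength on a 10 nm grid for the
end-to-end run (μa mean relative error tolerance 10% over 600–1000 nm),
100 replicates for the 1%-noise fixed-branch study (median-bias
tolerance 3%). Nelder–Mead runs to xatol 1e−10 in log coefficients;
Brent to rtol 1e−14; the bounded fits to L-BFGS-B ftol 1e−18.

## Known limitations

* The LUT forward model is pure Monte Carlo; there is no hybrid
  analytical acceleration, so building a LUT is the dominant cost
  (minutes, not seconds).
* Position-only sphere acceptance ignores exit angles and sphere
  multiple-bounce corrections; port diameters are configuration, not
  physics.
* The cylinder is homogeneous and single-layer; no polarization,
  fluorescence, or time-resolved transport.
* The fixed-μs′ branch inherits any bias of the predefined μs′
  one-to-one into μa; only its direction is guaranteed, not its size.
* The bundled colour tables are synthetic stand-ins (see above).
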