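"""Shared fixtures.

The expensive forward-model LUT for the finger cylinder is built once
per session and shared between the inversion tests; everything else is
cheap and generated per test from seeds.
"""

import numpy as np
import pytest

from fingerphantom.mc_transport import Geometry
from fingerphantom.sphere_lut import LUT, build_lut, default_grids
from fingerphantom.synthetic_data import make_finger_truth, make_pigment_basis

#: study-condition constants used across the suite
FINGER_GEOMETRY = Geometry.cylinder(13.8)
G = 0.75
N_IN = 1.4


@pytest.fixture(scope="session")
def cyl_lut():
    """16x16 cylinder LUT over the default coefficient ranges."""
    return build_lut(*default_grids(16, 16), FINGER_GEOMETRY,
                     g=G, n=N_IN, n_photons=25_000, max_photons=400_000,
                     seed=42)


@pytest.fixture(scope="session")
def small_lut():
    """Cheap 8x8 LUT for mechanics tests that don't need accuracy."""
    return build_lut(*default_grids(8, 8), FINGER_GEOMETRY,
                     g=G, n=N_IN, n_photons=5_000, max_photons=20_000,
                     seed=7)


@pytest.fixture(scope="session")
def analytic_lut():
    """LUT whose tables follow a smooth closed form (no Monte Carlo).

    R = 0.6 mus'^0.3 / (1 + 5 mu_a)^0.5, T = exp(-8 sqrt(mu_a (mu_a + mus')));
    exercises interpolation machinery against exactly known values.
    """
    mu_a = np.geomspace(1e-3, 2, 16)
    musr = np.geomspace(0.2, 6, 16)
    A, S = np.meshgrid(mu_a, musr, indexing="ij")
    R = 0.6 * S ** 0.3 / np.sqrt(1 + 5 * A)
    R = R / (R.max() * 1.01)  # keep fractions in (0, 1)
    T = np.exp(-8.0 * np.sqrt(A * (A + S)))
    zeros = np.zeros_like(R)
    return LUT(mu_a, musr, R, T, zeros, zeros, np.full_like(R, 1.0),
               meta={"analytic": True})


@pytest.fixture(scope="session")
def finger_truth():
    return make_finger_truth(seed=3)


@pytest.fixture(scope="session")
def pigment_fixture():
    return make_pigment_basis(seed=11)
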