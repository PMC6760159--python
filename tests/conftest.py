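"""Shared fixtures: standard simulated subregions and prior sets.

The "standard fixture" is a 16x16 subregion with five well-separated
emitters of ~2,000 photons each on a 20-photon background with a 1.2-px
Gaussian PSF -- the canonical convergence test conditions.
"""

import numpy as np
import pytest

from bamf.model import (
    SIGNAL,
    BackgroundPlane,
    EmitterSet,
    ModelState,
    PSFModel,
    PriorSet,
    Subregion,
    _LogIntensityKDE,
    emitter_pixel_counts,
)

FIVE_X = np.array([3.2, 11.5, 3.8, 11.2, 7.6])
FIVE_Y = np.array([3.5, 4.1, 11.8, 11.3, 7.4])


@pytest.fixture(scope="session")
def psf():
    return PSFModel(1.2)


@pytest.fixture(scope="session")
def intensity_kde():
    # empirical-style signal intensity prior centered near 2,000 photons
    rng = np.random.default_rng(2024)
    return _LogIntensityKDE(rng.gamma(50.0, 40.0, size=300))


@pytest.fixture(scope="session")
def priors(intensity_kde):
    return PriorSet(
        n_mean=5.0,
        offset_shape=80.0,
        offset_scale=0.25,
        signal_intensity=intensity_kde,
        bg_intensity_mean=400.0,
    )


def five_emitter_lambda(psf):
    region0 = Subregion(np.zeros((16, 16)), pad=2.0)
    lam = np.full((16, 16), 20.0)
    for x, y in zip(FIVE_X, FIVE_Y):
        lam += emitter_pixel_counts(x, y, 2000.0, psf, region0)
    return lam


@pytest.fixture(scope="session")
def five_emitter_region(psf):
    lam = five_emitter_lambda(psf)
    data = np.random.default_rng(1).poisson(lam)
    return Subregion(data.astype(float), pad=2.0)


@pytest.fixture()
def random_state():
    rng = np.random.default_rng(11)
    em = EmitterSet(
        rng.uniform(2, 13, 4),
        rng.uniform(2, 13, 4),
        rng.gamma(50.0, 40.0, 4),
        np.array([SIGNAL] * 4, dtype=np.int8),
    )
    return ModelState(em, BackgroundPlane(20.0, 0.1, -0.05))


@pytest.fixture(scope="session")
def flat_region():
    data = np.random.default_rng(0).poisson(25.0, size=(16, 16))
    return Subregion(data.astype(float), pad=2.0)
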