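"""Shared fixtures: noise-free synthetic subjects and their (slow) fits.

The two multi-start fits are session-scoped so that parameter-recovery,
round-trip and acceptance tests share one computation each.
"""

import numpy as np
import pytest

from aortamech.fitting import FitConfig, FourFiberModel
from aortamech.simulate import (
    DEFAULT_GEOMETRY,
    MURINE_ATA_PARAMS,
    NoiseModel,
    SimulationSpec,
    simulate_subject,
)


@pytest.fixture(scope="session")
def wt12_params():
    return MURINE_ATA_PARAMS[("WT", 12)]


@pytest.fixture(scope="session")
def mgd30_params():
    return MURINE_ATA_PARAMS[("mgdlpn", 30)]


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


def _noise_free_record(key, sample_id):
    spec = SimulationSpec(
        genotype=key[0], age_weeks=key[1], params=MURINE_ATA_PARAMS[key], noise=NoiseModel.none()
    )
    return simulate_subject(spec, sample_id, seed=0)


@pytest.fixture(scope="session")
def wt12_record():
    """Noise-free synthetic biaxial record of a representative wild-type vessel."""
    return _noise_free_record(("WT", 12), "wt12")


@pytest.fixture(scope="session")
def mgd30_record():
    """Noise-free record of the late-aneurysm Marfan-model vessel (vanishing axial family)."""
    return _noise_free_record(("mgdlpn", 30), "mgd30")


@pytest.fixture(scope="session")
def fit_config():
    return FitConfig(seed=7, n_starts=24)


@pytest.fixture(scope="session")
def wt12_fit(wt12_record, fit_config):
    return FourFiberModel.from_record(wt12_record).fit(fit_config)


@pytest.fixture(scope="session")
def mgd30_fit(mgd30_record, fit_config):
    return FourFiberModel.from_record(mgd30_record).fit(fit_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_params(rng, allow_zero=False):
    """A random admissible parameter set for property tests."""
    from aortamech.mech import FourFiberParams

    lo = 0.0 if allow_zero else 0.1
    return FourFiberParams.from_eight(
        rng.uniform(lo, 40),
        rng.uniform(lo, 30),
        rng.uniform(0, 3),
        rng.uniform(lo, 30),
        rng.uniform(0, 3),
        rng.uniform(lo, 30),
        rng.uniform(0, 3),
        rng.uniform(10, 80),
    )
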