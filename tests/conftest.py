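import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from devilray import McmcSettings, mobula_mobular, mobula_thurstoni
from devilray.synthetic_data import simulate_ages, simulate_specimens

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mobular():
    return mobula_mobular()


@pytest.fixture(scope="session")
def thurstoni():
    return mobula_thurstoni()


@pytest.fixture(scope="session")
def fast_mcmc():
    """Shorter chains for test fits; diagnostics thresholds unchanged."""
    return McmcSettings(n_steps=2500, n_burn=1000)


@pytest.fixture(scope="session")
def mobular_dataset(mobular):
    """Study-sized (n=79) noisy disc-width-at-age dataset, ages like the catch."""
    ages = simulate_ages(mobular, 79, seed=7)
    return simulate_specimens(mobular, ages, seed=7)


@pytest.fixture(scope="session")
def noisefree_thurstoni(thurstoni):
    """Noise-free dataset: deterministic sizes and weights."""
    profile = dataclasses.replace(thurstoni, sigma2_log=0.0, lw_sigma2_log=0.0)
    ages = simulate_ages(profile, 200, seed=11)
    return simulate_specimens(profile, ages, seed=11)
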