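import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bayespop as bp
from bayespop.io import (
    load_bangladesh_tfr,
    load_base_population_2001,
    load_default_asfr_pattern,
    load_published_projection,
    load_standard_schedules,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tfr_series() -> bp.TFRSeries:
    """The observed 11-point Bangladesh TFR series, 1991-2001."""
    return load_bangladesh_tfr()


@pytest.fixture(scope="session")
def standards():
    return load_standard_schedules()


@pytest.fixture(scope="session")
def base_population() -> bp.AgeSexPopulation:
    return load_base_population_2001()


@pytest.fixture(scope="session")
def asfr_pattern() -> np.ndarray:
    return load_default_asfr_pattern()


@pytest.fixture(scope="session")
def published_table():
    return load_published_projection()


@pytest.fixture(scope="session")
def quick_mcmc() -> bp.MCMCConfig:
    """Short run lengths for unit tests that only need a rough posterior."""
    return bp.MCMCConfig(n_chains=2, burn_in=2_000, n_iter=8_000, seed=42)


@pytest.fixture(scope="session")
def fitted_fertility_quick(tfr_series, quick_mcmc) -> bp.ChainSet:
    """One short fertility fit shared by several tests."""
    return bp.fit_fertility(tfr_series, mcmc=quick_mcmc)


def make_chainset(values, param_names=("x",)) -> bp.ChainSet:
    """Assemble a ChainSet directly from an array of draws.

    ``values`` has shape (n_chains, n_iter, n_params); used to build
    degenerate or hand-crafted ensembles in tests.
    """
    values = np.asarray(values, dtype=float)
    return bp.ChainSet(
        draws=values,
        param_names=tuple(param_names),
        acceptance_rates=np.full(values.shape[::2], np.nan),
        seed=0,
    )
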