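"""Shared fixtures.

The expensive fixture is ``scaled_fit``: the synthetic validation experiment
at half the units and a third of the time bins of the full design, fitted
once per session and shared by the recovery and acceptance tests.
"""

import numpy as np
import pytest

import stimtag as st

SCALED_SEED = 1


@pytest.fixture(scope="session")
def scaled_dataset():
    params = st.benchmark_preset(seed=SCALED_SEED, unit_scale=0.5, time_scale=0.3)
    table, truth = st.simulate_dataset(params, seed=SCALED_SEED)
    return params, table, truth


@pytest.fixture(scope="session")
def scaled_fit(scaled_dataset):
    params, table, truth = scaled_dataset
    config = st.ModelConfig(
        n_features=5, n_restarts=10, tol=1e-4, max_iter=300, seed=SCALED_SEED
    )
    result = st.fit(table, covariates=truth.covariates, config=config)
    return params, table, truth, result


@pytest.fixture(scope="session")
def tiny_fit():
    """A very small but fully converged fit for cheap posterior checks."""
    params = st.benchmark_preset(seed=7, unit_scale=0.2, time_scale=0.08)
    table, truth = st.simulate_dataset(params, seed=7)
    config = st.ModelConfig(
        n_features=3, n_restarts=2, tol=1e-5, max_iter=200, seed=7
    )
    result = st.fit(table, covariates=truth.covariates, config=config)
    return params, table, truth, result
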