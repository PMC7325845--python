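import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

import clv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_clv_params(rng):
    """A modest random cLV system with one perturbation (D=4)."""
    D, P = 4, 1
    return clv.CLVParams(
        g_rel=rng.normal(0, 0.3, D - 1),
        A_rel=rng.normal(0, 0.5, (D - 1, D)),
        B_rel=rng.normal(0, 0.3, (D - 1, P)),
        denominator=2,
    )


@pytest.fixture(scope="session")
def small_simulation():
    """One small simulated gLV community shared across tests (D=5)."""
    config = clv.SimulationConfig(D=5, n_subjects=6, n_timepoints=20, seed=7)
    dataset, glv_truth, clv_truth = clv.simulate_dataset(config)
    return config, dataset, glv_truth, clv_truth


def random_compositions(rng, n, D, concentration=2.0):
    return rng.dirichlet(np.full(D, concentration), size=n)
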