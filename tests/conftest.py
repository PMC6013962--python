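import numpy as np
import pytest

import maprkit as mk


@pytest.fixture(scope="session")
def eq5d():
    return mk.EQ5D3L


@pytest.fixture(scope="session")
def study_weights():
    return mk.STUDY_WEIGHTS_EQ5D3L


@pytest.fixture(scope="session")
def study_items():
    return list(mk.STUDY_ITEM_CODES)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_random_matrix(rng, P, I, beta_scale=1.0, theta_scale=1.0):
    """A random well-behaved response matrix for property tests."""
    from scipy.special import expit

    beta = rng.normal(0, beta_scale, I)
    theta = rng.normal(0, theta_scale, P)
    Y = (rng.random((P, I)) < expit(theta[:, None] - beta[None, :])).astype(np.int8)
    return mk.ResponseMatrix(
        persons=[f"p{i}" for i in range(P)],
        items=[f"i{j}" for j in range(I)],
        Y=Y,
    )


@pytest.fixture(scope="session")
def small_sim():
    """P=60, I=3 simulated matrix reused by the grid-search oracle tests."""
    sc = mk.SimulationScenario(
        item_codes=("a", "b", "c"),
        item_values=(0.0, -0.7, 0.9),
        n_persons=60,
        seed=42,
        persons=mk.PersonDistribution(family="normal", loc=0.0, scale=1.2),
    )
    return mk.simulate_responses(sc)
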