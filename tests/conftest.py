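import numpy as np
import pytest

import statedyn as sd


@pytest.fixture(scope="session")
def small_cohort() -> sd.SyntheticCohort:
    """12 subjects, 4 networks x 3 channels, 3 states; shared across tests."""
    return sd.simulate_cohort(sd.CohortConfig(
        n_subjects=12, n_timepoints=120, n_states=3,
        networks=("VisCent", "SomMotA", "ContA", "DefaultA"), seed=7,
    ))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_hmm_params(rng: np.random.Generator, n_states: int, n_channels: int):
    """Valid random HMM parameters for oracle fixtures."""
    start = rng.dirichlet(np.ones(n_states))
    trans = rng.dirichlet(np.ones(n_states), size=n_states)
    means = rng.normal(size=(n_states, n_channels))
    covs = np.empty((n_states, n_channels, n_channels))
    for k in range(n_states):
        a = rng.normal(size=(n_channels, n_channels))
        covs[k] = a @ a.T + n_channels * np.eye(n_channels)
    return start, trans, means, covs
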