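import numpy as np
import pytest

from unfoldkit import synthetic_data as syn


@pytest.fixture(scope="session")
def toy():
    """Native toy structure and its domain partition."""
    return syn.make_toy_two_domain_structure()


@pytest.fixture(scope="session")
def toy_structure(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_partition(toy):
    return toy[1]


@pytest.fixture(scope="session")
def two_state_run():
    """One short cooperative unfolding run with its truth record."""
    spec = syn.SyntheticSpec(seed=11, duration=1000.0, transition_time=400.0)
    traj, truth = syn.generate_unfolding_trajectory(spec)
    return traj, truth, spec


@pytest.fixture(scope="session")
def gradual_run():
    spec = syn.SyntheticSpec(
        seed=11, duration=1000.0, transition_time=400.0, mode="gradual"
    )
    traj, truth = syn.generate_unfolding_trajectory(spec)
    return traj, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
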