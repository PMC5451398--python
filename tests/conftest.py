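import numpy as np
import pytest

from isvs import SimParams, run_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_params():
    return SimParams()


@pytest.fixture(scope="session")
def small_experiment():
    """A modest default-parameter batch shared by classifier tests."""
    return run_experiment(SimParams(n_sims=120, master_seed=11))
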