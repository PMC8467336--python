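import numpy as np
import pytest

from msmnet import synthetic as syn


@pytest.fixture(scope="session")
def bead_top():
    return syn.bead_topology(8)


@pytest.fixture(scope="session")
def two_state_traj():
    """50k-frame two-basin trajectory with hidden labels (shared across tests)."""
    spec = syn.two_state_spec(seed=1)
    traj, labels = syn.generate_hmm_trajectory(spec, 50_000)
    return spec, traj, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
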