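import numpy as np
import pytest

from wmdecode import ChannelBasis, SimConfig, simulate_subject
from wmdecode.delay import extract_delay_patterns


@pytest.fixture(scope="session")
def basis():
    return ChannelBasis()


@pytest.fixture(scope="session")
def small_config():
    """A cheap study: 4 blocks x 18 trials, 12 voxels."""
    return SimConfig(n_subjects=2, n_blocks=4, n_voxels=12, seed=11)


@pytest.fixture(scope="session")
def small_subject(small_config):
    """One simulated subject with extracted delay patterns."""
    trials, runs, weights = simulate_subject(small_config, subject_seed=101)
    patterns = extract_delay_patterns(runs)
    return trials, runs, weights, patterns


def rng(seed=0):
    return np.random.default_rng(seed)
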