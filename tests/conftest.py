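import numpy as np
import pytest

from rloopmt.synthetic import SimParams, birth_death_rate_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_state_params():
    """Symmetric two-state chain at 0 / 1.8 turns, 1/s hopping."""
    q = np.array([[0.0, 1.0], [1.0, 0.0]])
    return SimParams(np.array([0.0, 1.8]), q, emission_sd=0.1,
                     sample_rate=60.0, seed=3)


@pytest.fixture
def five_state_params():
    """Five well-separated states for selection-recovery checks.

    Generated directly at the 10 Hz analysis rate so every sample is a
    clean state emission (no block-average smearing across transitions).
    """
    positions = np.array([0.0, 0.9, 1.3, 1.8, 2.0])
    occupancy = np.array([0.15, 0.2, 0.2, 0.25, 0.2])
    return SimParams(positions, birth_death_rate_matrix(occupancy, 0.5),
                     emission_sd=0.08, sample_rate=10.0, seed=4)
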