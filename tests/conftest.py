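import numpy as np
import pytest

from renalqct import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom_obs():
    """Default phantom simulation, one fixed seed."""
    return syn.simulate_phantom_observations(syn.PhantomSimConfig(), rng=7)


@pytest.fixture
def cohort():
    """Default cohort simulation, one fixed seed."""
    return syn.simulate_cohort(syn.CohortSimConfig(), rng=11)
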