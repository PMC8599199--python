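import numpy as np
import pytest

import critattract as ca


@pytest.fixture(scope="session")
def attracted_cohort():
    """Six simulated subjects at attraction factor 1.244, default design."""
    trials, params = ca.simulate_cohort(
        6,
        ca.gaussian_alpha_sampler(mean=1.244, sd=0.0, base_criteria=(-9, -6, -3, 3, 6, 9)),
        seed=101,
    )
    return trials, params


@pytest.fixture(scope="session")
def single_subject(attracted_cohort):
    trials, _ = attracted_cohort
    return trials[0]


@pytest.fixture(scope="session")
def balanced_subject(single_subject):
    kept, _ = ca.balance_trials(single_subject)
    return kept
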