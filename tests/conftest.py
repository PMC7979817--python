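import numpy as np
import pytest

from trialcpm import CohortConfig, generate_trial_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def strong_cohort():
    """Small cohort with strong planted coupling (per-edge r ~ 0.4)."""
    cfg = CohortConfig(
        n_participants=8,
        n_trials_per_participant=30,
        n_nodes=30,
        frac_pos_informative=0.1,
        frac_neg_informative=0.1,
        effect=0.436,
        edge_noise_sd=1.0,
        rating_noise_sd=0.0,
        seed=2024,
    )
    return generate_trial_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with zero edge-rating coupling."""
    cfg = CohortConfig(
        n_participants=6,
        n_trials_per_participant=25,
        n_nodes=20,
        frac_pos_informative=0.1,
        frac_neg_informative=0.1,
        effect=0.0,
        rating_noise_sd=15.0,
        seed=99,
    )
    return generate_trial_cohort(cfg)
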