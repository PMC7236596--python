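import numpy as np
import pytest

import emeskappa as ek


@pytest.fixture(scope="session")
def default_truth():
    return ek.sample_cohort(ek.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def zero_noise_table(default_truth):
    """13 raters reproducing the latent truth exactly."""
    return ek.simulate_ratings(
        default_truth, ek.RaterProfile(noise_sd=0.0), 13, seed=7
    )


@pytest.fixture(scope="session")
def noisy_table(default_truth):
    """13 raters at the calibrated (moderate-agreement) noise level."""
    return ek.simulate_ratings(
        default_truth, ek.RaterProfile(), 13, seed=7
    )


def random_count_matrix(rng, n_subjects=16, n_raters=13, K=4):
    """A study-like random count matrix: per-subject category profiles
    drawn from a Dirichlet around a common base, then multinomial."""
    base = rng.dirichlet(np.ones(K)) * K + 0.2
    counts = np.empty((n_subjects, K), dtype=np.int64)
    for i in range(n_subjects):
        p = rng.dirichlet(base * rng.uniform(1.0, 6.0))
        counts[i] = rng.multinomial(n_raters, p)
    return counts


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
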