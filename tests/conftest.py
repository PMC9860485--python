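import numpy as np
import pytest
from hypothesis import settings

from wardhmm.hmm import HMMParameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from wardhmm.synthetic import CohortConfig, sample_ground_truth, simulate_cohort


def random_hmm(K: int, D: int, rng: np.random.Generator) -> HMMParameters:
    """Small random valid HMM for oracle tests."""
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    means = rng.normal(scale=2.0, size=(K, D))
    covs = np.empty((K, D, D))
    for k in range(K):
        W = rng.normal(size=(D, D))
        covs[k] = W @ W.T / D + 0.3 * np.eye(D)
    return HMMParameters(pi=pi, A=A, means=means, covariances=covs)


@pytest.fixture(scope="session")
def small_ground_truth():
    return sample_ground_truth(K=3, D=5, separation=3.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """20 fully observable episodes with timestamped events."""
    config = CohortConfig(n_patients=20, K=3, D=23, separation=3.0, mean_length=6.0)
    episodes, gt = simulate_cohort(config, seed=42)
    return episodes, gt


@pytest.fixture(scope="session")
def latent_cohort():
    """120 episodes, latent matrices only (no event emission)."""
    config = CohortConfig(n_patients=120, K=3, D=23, separation=3.0, mean_length=8.0)
    episodes, gt = simulate_cohort(config, seed=5, emit=False)
    return episodes, gt
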