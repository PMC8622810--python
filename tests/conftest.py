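import numpy as np
import pytest

import gazehmm as gz


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_state_model():
    """Well-separated 2-ROI HMM used as a generating oracle."""
    return gz.HiddenMarkovModel(
        prior=[0.5, 0.5],
        transition=[[0.8, 0.2], [0.2, 0.8]],
        means=[[-8.0, 0.0], [8.0, 0.0]],
        covariances=[np.eye(2), np.eye(2)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort for unit tests."""
    cfg = gz.CohortConfig(n_participants_per_group=2, n_blocks=6, seed=7)
    return gz.simulate_cohort(cfg)


def random_model(rng, K):
    """A random valid HMM on the screen, for oracle comparisons."""
    prior = rng.dirichlet(np.ones(K))
    transition = rng.dirichlet(np.ones(K), size=K)
    means = rng.uniform(-10, 10, size=(K, 2))
    covs = []
    for _ in range(K):
        a = rng.normal(size=(2, 2))
        covs.append(a @ a.T + 0.5 * np.eye(2))
    return gz.HiddenMarkovModel(prior=prior, transition=transition,
                                means=means, covariances=np.stack(covs))


def brute_force_loglik(model, xy):
    """Path-enumeration log-likelihood: the independent oracle."""
    from itertools import product

    from scipy.stats import multivariate_normal as mvn

    T = len(xy)
    total = 0.0
    for path in product(range(model.K), repeat=T):
        p = model.prior[path[0]] * mvn.pdf(
            xy[0], model.means[path[0]], model.covariances[path[0]]
        )
        for t in range(1, T):
            p *= model.transition[path[t - 1], path[t]] * mvn.pdf(
                xy[t], model.means[path[t]], model.covariances[path[t]]
            )
        total += p
    return np.log(total)
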