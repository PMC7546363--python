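import numpy as np
import pytest

from gazehmm import PipelineConfig, ScreenGeometry, simulate_cohort


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-group cohort with short recordings for plumbing tests."""
    return simulate_cohort(group_sizes={"TD": 3, "ASD_ADHD": 2},
                           seed=123, recording_s=20.0,
                           recordings_per_class=1)


@pytest.fixture()
def config():
    return PipelineConfig(seed=99, restarts=2, elbo_rel_tol=1e-5)


def random_hmm(rng, K, D=2, spread=3.0):
    """A valid random point model for property tests."""
    from gazehmm.types import BhmmModel
    pi = rng.dirichlet(np.ones(K))
    A = np.array([rng.dirichlet(np.ones(K)) for _ in range(K)])
    means = rng.normal(0.0, spread, (K, D))
    covs = []
    for _ in range(K):
        M = rng.normal(0.0, 1.0, (D, D))
        covs.append(M @ M.T + np.eye(D) * 0.5)
    return BhmmModel(pi, A, means, np.array(covs))
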