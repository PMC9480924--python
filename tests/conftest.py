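import numpy as np
import pytest

from fcnet.network import ConnectivityMatrix
from fcnet.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SyntheticCohortConfig:
    """A desk-scale cohort: 16 nodes, 2 x 6 subjects, 80 timepoints."""
    return SyntheticCohortConfig(
        n_nodes=16, n_modules=4, t_points=80, n_per_group=6, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def random_weighted_graph(rng: np.random.Generator, n: int, density: float = 0.7):
    """Random symmetric nonnegative adjacency for oracle comparisons."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = rng.uniform(0.05, 1.0, iu[0].size) * (rng.random(iu[0].size) < density)
    w[iu] = vals
    return w + w.T


def as_rectified(weights: np.ndarray, subject_id: str = "s") -> ConnectivityMatrix:
    return ConnectivityMatrix(weights, stage="rectified", subject_id=subject_id)
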