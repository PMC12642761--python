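import numpy as np
import pytest

from adbc.graph import BrainGraph
from adbc.inference import FitConfig
from adbc.synthetic import CohortSpec, generate_cohort, generate_population_graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path3():
    """3-node path graph with unit weights."""
    A = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return BrainGraph(A)


@pytest.fixture
def small_pop():
    """Sparse connected 8-node population graph."""
    return generate_population_graph(CohortSpec(n_regions=8, seed=11))


def random_adjacency(rng, n):
    A = rng.random((n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


@pytest.fixture
def fast_fit_config():
    """Small budgets for unit tests of the fitting machinery."""
    return FitConfig(multistart=4, multistart_polish=2, maxiter_stage1=40,
                     maxiter_stage2=10, maxiter_stage3=10, maxiter_stage4=10, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two complete-data subjects on an 8-node graph, for pipeline tests."""
    spec = CohortSpec(n_subjects=2, n_regions=8, seed=5, missing_fraction={})
    pop, subjects = generate_cohort(spec)
    return spec, pop, subjects
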