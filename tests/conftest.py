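import numpy as np
import pytest
import scipy.sparse as sp


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def sparse_from_dense(a):
    return sp.csr_matrix(np.asarray(a, dtype=np.int8))


@pytest.fixture
def star5():
    """Star graph on 5 nodes, node 0 the center."""
    a = np.zeros((5, 5), dtype=np.int8)
    a[0, 1:] = a[1:, 0] = 1
    return a


@pytest.fixture
def complete5():
    a = np.ones((5, 5), dtype=np.int8)
    np.fill_diagonal(a, 0)
    return a


@pytest.fixture
def triangle_pendant():
    """Triangle 0-1-2 plus pendant node 3 attached to node 0."""
    a = np.zeros((4, 4), dtype=np.int8)
    for i, j in [(0, 1), (1, 2), (0, 2), (0, 3)]:
        a[i, j] = a[j, i] = 1
    return a


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared by slower tests."""
    from voxgraph.simulate import CohortSpec, generate_cohort

    spec = CohortSpec(n_young=4, n_old=4, run_lengths=(80, 100, 90), seed=11)
    return spec, generate_cohort(spec)
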