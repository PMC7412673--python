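import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

from hippo.counts import CountMatrix
from hippo.simulate import default_mixture_spec, simulate_poisson_mixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_counts(arr, gene_ids=None, cell_ids=None) -> CountMatrix:
    return CountMatrix(sp.csr_matrix(np.asarray(arr)), gene_ids or [], cell_ids or [])


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    return make_counts([[0, 0, 1, 1], [0, 0, 0, 0], [0, 0, 0, 10], [2, 2, 2, 2]])


@pytest.fixture(scope="session")
def small_mixture():
    """3 well-separated Poisson clusters, 100 cells each, 600 genes."""
    spec = default_mixture_spec(
        n_clusters=3, cells_per_cluster=100, n_genes=600, het_fraction=0.1, seed=7
    )
    m, labels = simulate_poisson_mixture(spec)
    return spec, m, labels


@pytest.fixture(scope="session")
def default_mixture():
    """The package's default droplet-style fixture (3x300 cells, 2000 genes)."""
    spec = default_mixture_spec(seed=11)
    m, labels = simulate_poisson_mixture(spec)
    return spec, m, labels
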