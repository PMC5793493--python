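import numpy as np
import pytest

from treelocus.synthdata import random_tree_gamma, t5_example
from treelocus.treespace import PhyloTree, Split


@pytest.fixture(scope="session")
def t5():
    """The explicit three-vertex configuration in T_5."""
    return t5_example()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def t5_point(xi1, xi2, xi3):
    """Tree at coordinates (xi1, xi2, xi3) in the T_5 example's orthants."""
    taxa = tuple(str(i) for i in range(6))
    edges = {}
    if xi1 > 0:
        edges[Split.from_indices((2, 3), 5)] = xi1
    elif xi1 < 0:
        edges[Split.from_indices((3, 4, 5), 5)] = -xi1
    if xi2 > 0:
        edges[Split.from_indices((4, 5), 5)] = xi2
    elif xi2 < 0:
        edges[Split.from_indices((2, 3, 4), 5)] = -xi2
    if xi3 > 0:
        edges[Split.from_indices((2, 3, 4, 5), 5)] = xi3
    return PhyloTree(taxa, edges)


@pytest.fixture(scope="session")
def random_trees():
    """A pool of small random trees (varying N) for property tests."""
    rng = np.random.default_rng(7)
    pool = {}
    for n in (5, 6, 8, 10):
        pool[n] = [random_tree_gamma(n, seed=rng) for _ in range(20)]
    return pool
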