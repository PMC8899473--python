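import itertools

import numpy as np
import pytest

from turriphylo import peptides, simulate
from turriphylo.phylo import DistanceMatrix, _path_length, leaf_path_between


@pytest.fixture(scope="session")
def reference_records():
    return peptides.load_reference_peptides()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tree_distance_matrix(tree) -> DistanceMatrix:
    """Additive (path-length) distance matrix of a tree — the oracle for
    neighbor-joining recovery tests."""
    names = sorted(tree.leaf_names())
    n = len(names)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = _path_length(leaf_path_between(tree, names[i], names[j]))
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=names, values=mat)


@pytest.fixture
def random_tree_factory():
    def _make(n_leaves: int, seed: int):
        return simulate.simulate_species_tree(n_leaves, seed=seed)

    return _make
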