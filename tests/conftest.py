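import numpy as np
import pytest

from microbeta import OtuTable, PhyloTree, to_presence, to_proportions
from microbeta.distances import branch_profiles


@pytest.fixture
def three_leaf_tree():
    """((A:1,B:1)I:1,C:1); — four branches of length 1."""
    return PhyloTree.from_newick("((A:1,B:1)I:1,C:1);")


@pytest.fixture
def three_otu_table():
    """Two samples: s1 = {A, B}, s2 = {A, C}, equal abundances."""
    return OtuTable(["s1", "s2"], ["A", "B", "C"], [[5, 5, 0], [5, 0, 5]])


@pytest.fixture
def three_leaf_profile(three_leaf_tree, three_otu_table):
    return branch_profiles(
        three_leaf_tree,
        to_proportions(three_otu_table),
        to_presence(three_otu_table),
    )


@pytest.fixture
def small_table():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(5, 8))
    counts[0, :4] = 0
    return OtuTable(
        [f"s{i}" for i in range(5)],
        [f"O{i}" for i in range(8)],
        counts,
    )


@pytest.fixture(scope="session")
def random_tree_tables():
    """Ten random (tree, table) fixtures over 12 OTUs for identity checks."""
    from microbeta.simulation import _random_subtree

    rng = np.random.default_rng(7)
    out = []
    for _ in range(10):
        names = [f"T{i}" for i in range(12)]
        root = _random_subtree(names, rng, scale=0.5)
        root.length = None
        tree = PhyloTree(root)
        counts = rng.integers(0, 30, size=(6, 12))
        counts[counts < 10] = 0  # sparsity
        counts[:, 0] += 1  # no all-zero sample
        table = OtuTable([f"s{i}" for i in range(6)], names, counts)
        out.append((tree, table))
    return out
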