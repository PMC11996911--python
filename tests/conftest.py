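import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly import CommunityTable


@pytest.fixture
def small_table():
    """4 samples x 5 OTUs with two clearly separated groups."""
    counts = pd.DataFrame(
        [[30, 20, 0, 0, 1],
         [28, 22, 1, 0, 0],
         [0, 0, 25, 25, 2],
         [1, 0, 24, 26, 0]],
        index=["S1", "S2", "S3", "S4"],
        columns=["O1", "O2", "O3", "O4", "O5"])
    return CommunityTable(counts)


@pytest.fixture
def five_tip_tree():
    return TreeNode.read(io.StringIO(
        "((A:1,B:2):0.5,((C:0.5,D:0.5):1,E:3):0.2):0.0;"))


@pytest.fixture
def star_tree():
    return TreeNode.read(io.StringIO("(A:1.5,B:1.5,C:1.5,D:1.5):0.0;"))


def random_table_and_tree(rng, n_tips=6, n_samples=4, max_count=20):
    """Random instance for oracle-equivalence property tests."""
    import dendropy
    labels = [f"T{i}" for i in range(n_tips)]
    tns = dendropy.TaxonNamespace(labels)
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=tns,
        rng=__import__("random").Random(int(rng.integers(1 << 30))))
    tree = TreeNode.read([dtree.as_string(schema="newick",
                                          suppress_rooting=True)])
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length <= 0:
            node.length = 0.1
    while True:
        counts = rng.integers(0, max_count, size=(n_samples, n_tips))
        if (counts.sum(axis=1) > 0).all():
            break
    table = CommunityTable(pd.DataFrame(
        counts, index=[f"S{i}" for i in range(n_samples)], columns=labels))
    return table, tree
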