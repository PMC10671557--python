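import numpy as np
import pytest

from molechron.io import read_labeled_tree
from molechron.models import GeneModel
from molechron.simulate import simulate_gene_alignment


def aged_tree(newick, ages_by_ntips):
    """Parse a labeled newick and assign node ages by clade size."""
    ltt = read_labeled_tree(newick)
    for nd in ltt.tree.preorder_node_iter():
        n = sum(1 for _ in nd.leaf_iter())
        nd.age_my = ages_by_ntips[n]
    ltt.validate()
    return ltt


@pytest.fixture
def four_taxon_tree():
    return aged_tree(
        "((A:0.0,B:0.0):0.0,(C:0.0,D:0.0):0.0);",
        {1: 0.0, 2: 20.0, 4: 40.0},
    )


@pytest.fixture
def gene_model():
    return GeneModel("TESTG", [120, 150, 90, 141])


@pytest.fixture
def clean_alignment(gene_model):
    return simulate_gene_alignment(gene_model, ["ref", "tx1", "tx2"], seed=7)


@pytest.fixture
def uniform_pi():
    return np.full(61, 1.0 / 61.0)
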