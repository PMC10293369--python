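import pytest

from haplodelim.io import Alignment, PhyloTree, SampleInfo, SampleTable
from haplodelim.simulate import make_demo_dataset


def make_alignment(pairs):
    """Alignment from a list of (id, sequence) pairs."""
    return Alignment(pairs)


@pytest.fixture(scope="session")
def demo():
    """Canned study-shaped fixture: (alignment, tree, samples, ledger)."""
    return make_demo_dataset(seed=7)


@pytest.fixture
def four_leaf_tree():
    return PhyloTree.from_newick("((A:1,B:1)0.99:1,(C:1,D:1)0.97:1);")


@pytest.fixture
def simple_samples():
    return SampleTable(
        [
            SampleInfo("A", "sp1", clade_label="left"),
            SampleInfo("B", "sp1", clade_label="left"),
            SampleInfo("C", "sp2", clade_label="right"),
            SampleInfo("D", "sp2", clade_label="right"),
        ]
    )
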