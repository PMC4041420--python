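import numpy as np
import pytest

from trnadyn.phylo import TreeIndex, read_newick
from trnadyn.simulate import simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


@pytest.fixture
def cherry_index():
    """Two tips, each at distance 1 from the root."""
    return TreeIndex(read_newick("(A:1.0,B:1.0);"))


@pytest.fixture
def five_tip_index():
    return TreeIndex(read_newick(
        "((A:0.2,B:0.2):0.5,((C:0.3,D:0.3):0.2,E:0.5):0.2);"))


@pytest.fixture
def medium_tree_index():
    """A 60-tip simulated ultrametric tree shared across tests."""
    return TreeIndex(simulate_tree(60, seed=424242))
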