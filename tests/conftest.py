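import numpy as np
import pytest

from morffokit.io_formats import PhyloTree


@pytest.fixture
def balanced_tree() -> PhyloTree:
    """4-taxon balanced tree, every branch length 1."""
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar_tree() -> PhyloTree:
    return PhyloTree.from_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
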