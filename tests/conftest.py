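import numpy as np
import pytest

import congevol as cv


@pytest.fixture
def quartet_tree():
    """Unrooted four-taxon tree with a short internal branch."""
    return cv.parse_newick("((FG:0.2,B:0.2):0.1,C:0.2,D:0.2);")


@pytest.fixture
def two_taxon_tree():
    return cv.parse_newick("(A:0.1,B:0.1);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
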