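import numpy as np
import pandas as pd
import pytest

from pangevo.trees import Tree


@pytest.fixture
def quartet_tree():
    """Rooted 4-leaf balanced tree with labelled internal nodes."""
    return Tree.from_newick("((A,B)N1,(C,D)N2)R;")


@pytest.fixture
def pair_tree():
    return Tree.from_newick("(A:0.2,B:0.2);")


@pytest.fixture
def binary_pattern():
    def make(values):
        return pd.DataFrame({"c1": values}, index=list("ABCD"))

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
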