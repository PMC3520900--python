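import numpy as np
import pytest

from cladebin import read_newick
from cladebin.synthetic import default_study_scenario
from cladebin.tree_core import random_tree


@pytest.fixture
def cherry4():
    """((A,B),(C,D)) with unit-ish branch lengths."""
    return read_newick("((A:1,B:2):0.5,(C:1.5,D:0.7):0.5);")


@pytest.fixture
def tree3():
    return read_newick("(A:1,(B:2,C:3):4);")


@pytest.fixture(scope="session")
def scenario():
    """Default study-design scenario (21 ref / 65 query / 24 chars)."""
    return default_study_scenario(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_tree(n, rng):
    """Helper: random rooted binary tree with exponential lengths."""
    labels = [f"t{i}" for i in range(n)]
    pool = rng.exponential(1.0, size=2 * n - 2)
    return random_tree(labels, pool, rng)
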