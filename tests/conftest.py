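import logging

import dendropy
import numpy as np
import pytest

from cladespec import synthetic

logging.getLogger("cladespec").setLevel(logging.ERROR)


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the standard worked covariance example."""
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return tree_from_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def yule50():
    """A fixed 50-tip unit-height clade shared by the simulation tests."""
    return synthetic.simulate_yule_tree(50, np.random.default_rng(12))


def random_tree(n: int, seed: int) -> dendropy.Tree:
    return synthetic.simulate_yule_tree(n, np.random.default_rng(seed))
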