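import numpy as np
import pytest

from pathscape.simulate import SimSpec, random_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_pair(n_leaves, rng, mean_length=0.1):
    spec = SimSpec(n_leaves=n_leaves, branch_dist=("exponential", mean_length))
    return random_tree(spec, rng), random_tree(spec, rng)


@pytest.fixture
def quartet_pair():
    """The classic incompatible quartet pair AB|CD vs AC|BD."""
    from pathscape.treeio import parse_newick

    t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
    return t1, t2
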