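import numpy as np
import pytest

from mkasr import mk, synthetic, treeio


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def balanced_tree():
    return treeio.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


def random_tree(rng, n_tips, depth=2.0):
    return synthetic.simulate_yule_tree(
        int(n_tips), depth, seed=int(rng.integers(2**31 - 1))
    )


def random_tips(rng, tree, k, allow_missing=False):
    states = {}
    for lab in tree.tip_labels:
        if allow_missing and rng.random() < 0.2:
            states[lab] = mk.MISSING
        else:
            states[lab] = int(rng.integers(k))
    return mk.TipStates(k=k, states=states)
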