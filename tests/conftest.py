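import warnings

import numpy as np
import pytest

from ouregimes import read_newick
from ouregimes.synth import (SyntheticStudyConfig, build_synthetic_study,
                             simulate_yule_tree, simulate_regime_history)


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree():
    return read_newick("((A:0.2,B:0.3):0.1,(C:0.15,D:0.4):0.2);")


@pytest.fixture(scope="session")
def small_study():
    """A 60-tip synthetic study reused across tests (read-only)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_synthetic_study(SyntheticStudyConfig(n_tips=60, seed=3))


@pytest.fixture(scope="session")
def painted_tree_200():
    """A 200-tip Yule tree with a three-regime history (read-only)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tree = simulate_yule_tree(200, seed=7)
        node_states, painting = simulate_regime_history(tree, 0.6, seed=8)
    return tree, node_states, painting


def random_painted_tree(rng, n_tips, n_regimes=3):
    """Random Yule tree with a painting that uses every regime (test helper)."""
    from ouregimes.tree import RegimePainting

    tree = simulate_yule_tree(n_tips, seed=int(rng.integers(2**31)))
    while True:
        regime = rng.integers(n_regimes, size=tree.n_nodes)
        tips_used = {int(regime[t]) for t in tree.tips}
        if len(tips_used) == n_regimes:
            break
    alphabet = tuple(f"r{i}" for i in range(n_regimes))
    painting = RegimePainting(regime, alphabet, int(regime[tree.root]))
    return tree, painting
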