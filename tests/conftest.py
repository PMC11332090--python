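import numpy as np
import pytest

import phylofactory as pf


@pytest.fixture
def four_tip_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — the worked-example balanced tree."""
    return pf.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def yule200():
    """A 200-tip pure-birth tree shared by slower statistical tests."""
    return pf.simulate_birth_death_tree(200, birth=1.0, death=0.0, seed=777)


def random_tree(n_tips: int, seed: int):
    return pf.simulate_birth_death_tree(n_tips, birth=1.0, death=0.0, seed=seed)


def random_tree_positive(n_tips: int, seed: int, min_blen: float = 0.05):
    """A simulated tree with every branch length >= min_blen.

    Birth-death simulators stop mid-event and can leave zero-length
    cherries; raising those to a floor keeps probability-zero trait
    configurations out of likelihood-oracle comparisons.
    """
    tree = random_tree(n_tips, seed)
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = max(float(node.edge.length or 0.0), min_blen)
    return pf.parse_newick(tree.to_newick())


def random_binary_states(labels, k: int, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    ones = set(rng.choice(len(labels), size=k, replace=False).tolist())
    return {lab: int(i in ones) for i, lab in enumerate(labels)}
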