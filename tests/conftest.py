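import numpy as np
import pandas as pd
import pytest

from commphylo import CommunityMatrix, SimConfig, cophenetic_distances, gen_tree
from commphylo.trees import tree_from_newick

FOUR_TIP_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture(scope="session")
def four_tip_tree():
    return tree_from_newick(FOUR_TIP_NEWICK)


@pytest.fixture(scope="session")
def four_tip_dist(four_tip_tree):
    return cophenetic_distances(four_tip_tree)


@pytest.fixture
def random_tree_factory():
    """Yule trees of a given size, reproducible per seed."""

    def make(n_tips: int, seed: int):
        return gen_tree(SimConfig(n_species=n_tips, seed=seed))

    return make


@pytest.fixture
def random_matrix_factory():
    """Random binary community matrices over a tree's tips."""

    def make(tree, n_sites: int, richness: int, seed: int) -> CommunityMatrix:
        rng = np.random.default_rng(seed)
        T = tree.n_tips
        presence = np.zeros((n_sites, T), dtype=np.int8)
        for s in range(n_sites):
            presence[s, rng.choice(T, size=richness, replace=False)] = 1
        df = pd.DataFrame(
            presence, index=[str(100 * (s + 1)) for s in range(n_sites)],
            columns=tree.tip_labels,
        )
        return CommunityMatrix(df)

    return make
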