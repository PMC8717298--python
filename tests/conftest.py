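import dendropy
import numpy as np
import pytest

from phylodom.synthetic import ScenarioConfig, simulate_dataset, simulate_tree
from phylodom.trees import TreeIndex

T4_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


def tree_from(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


@pytest.fixture
def t4():
    return tree_from(T4_NEWICK)


@pytest.fixture
def t4_index(t4):
    return TreeIndex(t4)


@pytest.fixture(scope="session")
def clustered_ds():
    return simulate_dataset(ScenarioConfig(
        scenario="clustered_dominants", n_sites=20, n_species_pool=150, seed=7))


@pytest.fixture(scope="session")
def neutral_ds():
    return simulate_dataset(ScenarioConfig(
        scenario="neutral", n_sites=20, n_species_pool=150, seed=5))


@pytest.fixture(scope="session")
def pool_tree():
    return simulate_tree(60, seed=17)


def random_ultrametric(n_tips: int, seed: int):
    return simulate_tree(n_tips, seed=seed).tree


@pytest.fixture
def rng():
    return np.random.default_rng(0)
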