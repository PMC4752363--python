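import dendropy
import numpy as np
import pytest

from ovotrait.simulate import SimulationConfig, simulate_species_dataset
from ovotrait.trees import simulate_yule_tree, tree_covariance


@pytest.fixture(scope="session")
def three_taxon_tree():
    """((A:1,B:1):1,C:2) — the standard hand-computable covariance example."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture(scope="session")
def yule71():
    """A fixed 71-tip pure-birth tree with its covariance matrix."""
    tree = simulate_yule_tree(71, birth_rate=1.0, seed=71)
    V, labels = tree_covariance(tree)
    return tree, V, labels


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study (20 species x 2 eggs)."""
    cfg = SimulationConfig(
        seed=11, n_species=20, n_replicates=2,
        canvas_height=200, canvas_width=260,
    )
    return simulate_species_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
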