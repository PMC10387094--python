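import numpy as np
import pytest

from cladedensity import PhyloTree, read_newick
from cladedensity.synthetic import ScenarioConfig, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def three_tip_tree() -> PhyloTree:
    return read_newick("((A:0.5,B:0.5):0.5,C:1);")


@pytest.fixture
def balanced_four_tip_tree() -> PhyloTree:
    return read_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")


def random_tree(n_tips: int, seed: int, death_rate: float = 0.0) -> PhyloTree:
    """A random ultrametric birth-death tree for property tests."""
    cfg = ScenarioConfig(
        n_tips=n_tips, death_rate=death_rate, seed=seed
    )
    tree, _ = simulate_tree(cfg, np.random.default_rng(seed))
    return tree
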