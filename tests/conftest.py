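import numpy as np
import pytest

from hostflux.simulate import SimulationConfig, simulate_host_phylogeny
from hostflux.tree import Tree


@pytest.fixture
def quartet_tree() -> Tree:
    tree = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    tree.relabel_internal()
    return tree


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=0, n_genomes=12, n_lineages=3,
                            n_core_genes=4, gene_length=200,
                            root_family_count=120, innovation_rate=10.0)


@pytest.fixture
def small_world(small_config):
    tree, truth = simulate_host_phylogeny(small_config)
    return tree, truth, small_config


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m
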