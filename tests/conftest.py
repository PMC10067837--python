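import io

import pytest
from skbio import TreeNode

from halocog.clustering import (
    all_vs_all_similarity,
    greedy_cluster,
    refine_clusters,
)
from halocog.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """10 genomes x 20 families with clear within/between-family identity
    contrast; shared across clustering and signature tests."""
    cfg = SimulationConfig(n_genomes=10, n_families=20, seed=3)
    tree, matrix, truth, genomes = simulate_all(cfg)
    return cfg, tree, matrix, truth, genomes


@pytest.fixture(scope="session")
def small_refined(small_sim):
    _, _, _, _, genomes = small_sim
    hits = all_vs_all_similarity(genomes.records)
    initial = greedy_cluster(hits, genomes.records)
    refined, log = refine_clusters(initial)
    return refined, log


def read_tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))
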