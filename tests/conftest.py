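import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the reference oracles

from pangtm.simulate import SimulationConfig, simulate_pangenome  # noqa: E402


def small_config(**overrides) -> SimulationConfig:
    """A desk-scale simulation: 8 strains, 70 families, 3 planted clusters."""
    defaults = dict(
        n_strains=8,
        core_size=30,
        n_dispensable=40,
        n_trait_clusters=3,
        cluster_size_range=(3, 5),
        unique_per_strain_range=(0, 4),
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """(config, genomes, annotations, truth) for the small simulation."""
    cfg = small_config()
    genomes, annotations, truth = simulate_pangenome(cfg)
    return cfg, genomes, annotations, truth


@pytest.fixture(scope="session")
def default_sim():
    """The full-scale study conditions: 20 strains, 400 core + 600 dispensable."""
    cfg = SimulationConfig(seed=11)
    genomes, annotations, truth = simulate_pangenome(cfg)
    return cfg, genomes, annotations, truth


def random_weighted_graph(seed: int, max_nodes: int = 30) -> nx.Graph:
    """Seeded random weighted graph for clustering equivalence tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, max_nodes + 1))
    p = float(rng.uniform(0.1, 0.5))
    g = nx.Graph()
    g.add_nodes_from(f"n{i:02d}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"n{i:02d}", f"n{j:02d}",
                           weight=float(rng.uniform(0.1, 2.0)))
    return g
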