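import numpy as np
import pytest

import multimorb as mm


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def lattice_2x2():
    return mm.build_lattice_graph(2, 2)


@pytest.fixture
def lattice_10x10():
    return mm.build_lattice_graph(10, 10)


@pytest.fixture(scope="session")
def toy_dataset():
    """Small synthetic dataset (4x4 lattice) shared by model-level tests."""
    return mm.simulate_dataset(mm.SyntheticConfig(n_rows=4, n_cols=4, seed=11))


def random_graph(n_areas: int, rng: np.random.Generator, p: float = 0.4) -> mm.AdjacencyGraph:
    """Random symmetric graph with at least one edge, for brute-force cross-checks."""
    while True:
        edges = [
            (a, b)
            for a in range(n_areas)
            for b in range(a + 1, n_areas)
            if rng.random() < p
        ]
        if edges:
            return mm.AdjacencyGraph(n_areas, tuple(edges))
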