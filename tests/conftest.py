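import numpy as np
import networkx as nx
import pytest

from gscomod import (
    DiseaseGeneSet,
    GeneSet,
    GeneSetCollection,
    make_no_overlap_benchmark,
    profile,
)


@pytest.fixture
def small_collection() -> GeneSetCollection:
    """Four functional sets over a 12-gene universe, hand-checkable."""
    universe = [f"G{i}" for i in range(12)]
    sets = [
        GeneSet("S1", frozenset({"G0", "G1", "G2", "G3"})),
        GeneSet("S2", frozenset({"G2", "G3", "G4", "G5"})),
        GeneSet("S3", frozenset({"G6", "G7", "G8"})),
        GeneSet("S4", frozenset({"G9", "G10", "G11"})),
    ]
    return GeneSetCollection.from_sets(sets, universe=universe, collection_id="toy")


@pytest.fixture
def path_net() -> nx.Graph:
    """Path graph A - B - C - D."""
    g = nx.path_graph(4)
    return nx.relabel_nodes(g, {0: "A", 1: "B", 2: "C", 3: "D"})


@pytest.fixture(scope="session")
def no_overlap_benchmark():
    """60-pair gene-disjoint benchmark (20 functionally comorbid) with
    precomputed semantic profiles; shared across tests for speed."""
    collection, diseases, pairs, labels = make_no_overlap_benchmark(seed=11)
    profiles = {d: profile(ds, collection) for d, ds in diseases.items()}
    return collection, diseases, pairs, labels, profiles


def two_line_data(seed: int, n: int = 200, sigma: float = 0.05):
    """Synthetic two-component regression benchmark: half the points on
    y = x, half on y = -0.5x + 2, Gaussian noise. Returns x, y, labels."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 5.0, n)
    labels = (np.arange(n) >= n // 2).astype(int)
    y = np.where(labels == 0, 1.0 * x, -0.5 * x + 2.0) + rng.normal(0.0, sigma, n)
    return x, y, labels
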