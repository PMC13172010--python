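import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gutnet.abundance import AbundanceTable
from gutnet.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset reused by read-only tests."""
    return generate_dataset(SyntheticSpec(n_taxa=15, n_samples=120, seed=42))


@pytest.fixture
def toy_table():
    rng = np.random.default_rng(7)
    vals = rng.dirichlet(np.ones(8), size=12)
    df = pd.DataFrame(
        vals,
        index=[f"s{i}" for i in range(12)],
        columns=[f"t{i}" for i in range(8)],
    )
    meta = pd.DataFrame({"group": ["A"] * 6 + ["B"] * 6}, index=df.index)
    return AbundanceTable(values=df, metadata=meta)


def weighted_graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, sign="+" if w >= 0 else "-")
    return g


@pytest.fixture
def star9():
    """Star with 9 leaves (10 nodes), unit positive weights."""
    return weighted_graph([("c", f"l{i}", 1.0) for i in range(9)])


@pytest.fixture
def k10():
    g = nx.complete_graph(10)
    nx.set_edge_attributes(g, 1.0, "weight")
    return g
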