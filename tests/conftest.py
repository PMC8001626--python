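import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conet import SyntheticSpec, generate_counts


@pytest.fixture(scope="session")
def small_dataset():
    """A 100-taxon dataset with 4 planted guilds, shared across tests."""
    spec = SyntheticSpec(
        n_samples=36,
        n_taxa=100,
        n_guilds=4,
        guild_size=10,
        within_guild_rho=0.9,
        n_env_params=3,
        env_linked_guilds=(0, 1),
        noise_taxa_fraction=0.2,
        seed=1,
    )
    counts, env, truth = generate_counts(spec)
    return spec, counts, env, truth


@pytest.fixture
def toy_counts():
    df = pd.DataFrame(
        [[5, 0, 3, 1], [0, 0, 0, 2], [10, 20, 5, 8]],
        index=["a", "b", "c"],
        columns=["s1", "s2", "s3", "s4"],
    )
    df.index.name = "id"
    return df


def random_graph(rng: np.random.Generator, n_max: int = 12) -> nx.Graph:
    """Random small graph for oracle-equivalence testing."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.7))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
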