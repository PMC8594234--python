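import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gutnet as gn

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_counts() -> gn.CountMatrix:
    """3 taxa x 4 samples with distinctive integer patterns."""
    table = pd.DataFrame(
        [[10, 0, 3, 7], [0, 5, 5, 5], [1, 1, 1, 1]],
        index=pd.Index(["tA", "tB", "tC"], name="taxon_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    return gn.CountMatrix(table)


@pytest.fixture
def small_design() -> gn.SampleDesign:
    table = pd.DataFrame(
        {
            "diet": ["U", "U", "G", "G"],
            "region": ["eso", "sto", "eso", "sto"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return gn.SampleDesign(table)


@pytest.fixture
def one_edge_network() -> gn.AssociationNetwork:
    edges = pd.DataFrame(
        [
            {
                "source": "tA",
                "target": "tB",
                "weight": 0.62,
                "sign": "co-occurrence",
                "p_value": 0.004975124378109453,
            }
        ]
    )
    return gn.AssociationNetwork(("tA", "tB", "tC"), edges, provenance="overall")


def random_graph_instances(n_graphs=30, max_nodes=8, seed=0):
    """Connected-or-not random graphs for oracle comparisons."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(n_graphs):
        n = int(rng.integers(3, max_nodes + 1))
        p = float(rng.uniform(0.2, 0.8))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        graphs.append(g)
    return graphs
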