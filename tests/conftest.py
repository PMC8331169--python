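import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hausnet.io import CountMatrix


@pytest.fixture
def tiny_counts(tmp_path):
    """2-gene x 2-sample count file with its metadata file."""
    counts = tmp_path / "counts.tsv"
    counts.write_text("gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\n")
    meta = tmp_path / "meta.tsv"
    meta.write_text("sample_id\ttissue_class\treplicate\ns1\tstem\t1\ns2\tstem\t2\n")
    return counts, meta


@pytest.fixture
def nb_counts():
    """Random negative-binomial count matrix with metadata (seeded)."""
    rng = np.random.default_rng(20240817)
    mu = np.exp(rng.normal(4.5, 1.0, size=200))
    counts = rng.negative_binomial(10, 10 / (10 + mu[:, None]), size=(200, 6))
    genes = [f"g{i:03d}" for i in range(200)]
    samples = [f"s{j}" for j in range(6)]
    meta = pd.DataFrame(
        {"tissue_class": ["a", "a", "b", "b", "c", "c"], "replicate": list("121212")},
        index=pd.Index(samples, name="sample_id"),
    )
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta)


@pytest.fixture
def two_clique_bridge():
    """Two 4-cliques joined by one bridge edge; known modularity optimum."""
    g = nx.Graph()
    for base in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(base + i, base + j)
    g.add_edge(0, 4)
    return g


# Fixtures where greedy agglomeration is known to stop short of the global
# modularity optimum (networkx's CNM returns the same partitions).  The
# greedy Q and the exhaustive optimum are both frozen so any drift is caught.
KNOWN_SUBOPTIMAL_Q = {
    "path8": (0.3571428571428571, 0.37755102040816324),
    "random8a": (0.2716049382716049, 0.2901234567901234),
}


@pytest.fixture
def small_graph_suite(two_clique_bridge):
    """Named graphs of <= 8 nodes for exhaustive-oracle comparisons."""
    rng = np.random.default_rng(7)
    graphs = {
        "two_cliques_bridge": two_clique_bridge,
        "triangles": nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]),
        "complete5": nx.complete_graph(5),
        "path8": nx.path_graph(8),
        "cycle7": nx.cycle_graph(7),
        "star7": nx.star_graph(6),
        "random8a": nx.gnp_random_graph(8, 0.35, seed=3),
        "random8b": nx.gnp_random_graph(8, 0.5, seed=11),
    }
    return graphs
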