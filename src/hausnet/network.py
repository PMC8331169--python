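"""Gene coexpression networks and their community / centrality analysis.

A network is built by thresholding pairwise Pearson correlations.  The
"normal quantile" rule Fisher-transforms all off-diagonal correlations
(z = atanh r), fits a normal distribution by their mean and sd, and keeps
pairs whose z exceeds mean + Φ⁻¹(q)·sd; the empirical rule thresholds at
the empirical q-quantile of r.  Both record the realized cutoff.

Communities come from greedy (CNM) modularity maximization, written here
with an explicit merge history and deterministic tie-breaking: starting
from singletons, the connected community pair with the largest modularity
gain ΔQ is merged, and the partition returned is the merge-history state
with maximal Q.  Modularity is computed on the unweighted thresholded
topology,

    Q = Σ_c ( m_c / m − (d_c / 2m)² ),

with m_c within-community edges and d_c the community degree sum.
Hubs are ranked by degree, then betweenness (Brandes, unnormalized,
endpoints excluded), then id.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "CoexpressionNetwork",
    "ModulePartition",
    "ThresholdRecord",
    "pearson_matrix",
    "spearman_matrix",
    "build_gcn",
    "fast_greedy_partition",
    "modularity",
    "centrality_scores",
    "ego_layers",
    "hub_ranking",
    "write_edge_list",
    "write_node_table",
]

_ATANH_CLIP = 1.0 - 1e-12


@dataclass
class ThresholdRecord:
    method: str
    quantile: float
    cutoff: float             # realized cutoff on the method's scale
    cutoff_scale: str         # "fisher_z" or "r"
    n_candidate_pairs: int
    n_edges: int
    z_mean: float | None = None
    z_sd: float | None = None


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph           # nodes = gene ids; edge attr 'weight' = r
    threshold_record: ThresholdRecord

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ModulePartition:
    labels: pd.Series              # node -> module label, 1-based, by size
    modularity_q: float
    merge_history: list[tuple[tuple[str, str], float, float]] = field(
        default_factory=list
    )  # ((min-id of A, min-id of B), dQ, Q after merge)

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0


def pearson_matrix(sm, genes=None) -> pd.DataFrame:
    """Pairwise Pearson correlation of gene profiles (rows)."""
    vals = sm.values if genes is None else sm.values.loc[list(genes)]
    if vals.shape[1] < 3:
        raise ValueError("correlation needs at least 3 columns")
    arr = vals.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = vals.index[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance gene {bad!r}; filter before correlating")
    corr = np.corrcoef(arr)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=vals.index, columns=vals.index)


def spearman_matrix(sm, genes=None) -> pd.DataFrame:
    """Spearman rank correlation alternative (configurable metric)."""
    vals = sm.values if genes is None else sm.values.loc[list(genes)]
    if vals.shape[1] < 3:
        raise ValueError("correlation needs at least 3 columns")
    ranked = np.apply_along_axis(rankdata, 1, vals.to_numpy(dtype=float))
    corr = np.clip(np.corrcoef(ranked), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=vals.index, columns=vals.index)


def build_gcn(corr: pd.DataFrame, q: float, method: str = "normal") -> CoexpressionNetwork:
    """Threshold a correlation matrix into an undirected coexpression graph.

    ``method='normal'``: fit a normal to the Fisher-z of all off-diagonal
    upper-triangle correlations and cut at mean + Φ⁻¹(q)·sd (on the z
    scale).  ``method='empirical'``: cut at the empirical q-quantile of r.
    Edge weights are the correlations; every node is kept, so genes whose
    correlations all fall below the cutoff remain as isolated nodes.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    genes = list(corr.index)
    arr = corr.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    r = arr[iu, ju]

    if method == "normal":
        z = np.arctanh(np.clip(r, -_ATANH_CLIP, _ATANH_CLIP))
        sd = float(z.std(ddof=1))
        if sd == 0.0 or r.size < 2:
            raise ValueError("all correlations identical; cannot fit a normal cutoff")
        mean = float(z.mean())
        cutoff = mean + norm.ppf(q) * sd
        keep = z > cutoff
        record = ThresholdRecord(
            method="normal", quantile=q, cutoff=float(cutoff),
            cutoff_scale="fisher_z", n_candidate_pairs=int(r.size),
            n_edges=int(keep.sum()), z_mean=mean, z_sd=sd,
        )
    elif method == "empirical":
        # inverse-ECDF quantile: keep the top ceil((1-q)*n) pairs, so the
        # q -> 0 limit is the complete graph and edge sets nest exactly
        n_keep = int(np.ceil((1.0 - q) * r.size))
        cutoff = float(np.sort(r)[r.size - n_keep])
        keep = r >= cutoff
        record = ThresholdRecord(
            method="empirical", quantile=q, cutoff=cutoff, cutoff_scale="r",
            n_candidate_pairs=int(r.size), n_edges=int(keep.sum()),
        )
    else:
        raise ValueError("method must be 'normal' or 'empirical'")

    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, j, w in zip(iu[keep], ju[keep], r[keep]):
        g.add_edge(genes[i], genes[j], weight=float(w))
    return CoexpressionNetwork(graph=g, threshold_record=record)


def modularity(g: nx.Graph, labels: pd.Series) -> float:
    """Q = Σ_c (m_c/m − (d_c/2m)²) on the unweighted topology."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for module in labels.unique():
        nodes = set(labels.index[labels == module])
        mc = sum(1 for u, v in g.edges(nodes) if u in nodes and v in nodes)
        dc = sum(d for _, d in g.degree(nodes))
        q += mc / m - (dc / (2.0 * m)) ** 2
    return q


def fast_greedy_partition(net) -> ModulePartition:
    """Agglomerative (CNM) modularity maximization with merge history.

    Starting from singleton communities, the connected pair with maximal
    ΔQ = m_AB/m − 2·(d_A/2m)(d_B/2m) is merged at each step (ties broken
    by the lexicographically smallest pair of smallest member ids); the
    returned partition is the merge-history state with maximal Q.
    Isolated nodes never merge and survive as singleton modules.
    Modules are relabeled by decreasing size, then smallest member id.
    """
    g = net.graph if isinstance(net, CoexpressionNetwork) else net
    nodes = sorted(g.nodes)
    if not nodes:
        return ModulePartition(labels=pd.Series(dtype=int), modularity_q=0.0)
    m = g.number_of_edges()
    if m == 0:
        labels = pd.Series(range(1, len(nodes) + 1), index=nodes, name="module")
        return ModulePartition(labels=labels, modularity_q=0.0)

    comm_of = {v: i for i, v in enumerate(nodes)}
    members: dict[int, set] = {i: {v} for i, v in enumerate(nodes)}
    min_id: dict[int, str] = {i: v for i, v in enumerate(nodes)}
    deg_sum = {i: g.degree(v) for i, v in enumerate(nodes)}
    within = {i: 0 for i in members}
    between: dict[int, dict[int, int]] = {i: {} for i in members}
    for u, v in g.edges:
        a, b = comm_of[u], comm_of[v]
        if a == b:
            within[a] += 1
        else:
            between[a][b] = between[a].get(b, 0) + 1
            between[b][a] = between[b].get(a, 0) + 1

    two_m = 2.0 * m
    q = sum(within[c] / m - (deg_sum[c] / two_m) ** 2 for c in members)
    best_q = q
    best_labels = dict(comm_of)
    history: list[tuple[tuple[str, str], float, float]] = []

    while True:
        best = None  # (dq, (lo,hi) of min member ids, a, b)
        for a, nbrs in between.items():
            for b, e_ab in nbrs.items():
                if b <= a:
                    continue
                dq = e_ab / m - 2.0 * (deg_sum[a] / two_m) * (deg_sum[b] / two_m)
                ids = tuple(sorted((min_id[a], min_id[b])))
                key = (-dq, ids)
                if best is None or key < best[0]:
                    best = (key, a, b)
        if best is None:
            break
        (neg_dq, ids), a, b = best
        dq = -neg_dq
        # merge b into a
        members[a] |= members.pop(b)
        min_id[a] = min(min_id[a], min_id.pop(b))
        within[a] += within.pop(b) + between[a].pop(b)
        deg_sum[a] += deg_sum.pop(b)
        for c, e_bc in between.pop(b).items():
            if c == a:
                continue
            between[c].pop(b)
            between[a][c] = between[a].get(c, 0) + e_bc
            between[c][a] = between[a][c]
        q += dq
        history.append((ids, dq, q))
        if q > best_q + 1e-12:
            best_q = q
            best_labels = {v: a for a, vs in members.items() for v in vs}

    # relabel best state: decreasing size, then smallest member id
    groups: dict[int, list] = {}
    for v, c in best_labels.items():
        groups.setdefault(c, []).append(v)
    ordered = sorted(groups.values(), key=lambda vs: (-len(vs), min(vs)))
    labels = pd.Series(
        {v: i + 1 for i, vs in enumerate(ordered) for v in vs}, name="module"
    ).reindex(nodes)
    q_check = modularity(g, labels)
    assert abs(q_check - best_q) < 1e-9
    return ModulePartition(labels=labels.astype(int), modularity_q=q_check,
                           merge_history=history)


def centrality_scores(net) -> pd.DataFrame:
    """Degree and betweenness centrality per gene.

    Betweenness is Brandes' pair-dependency accumulation on unweighted
    shortest paths, unnormalized with endpoints excluded (ranking is what
    matters downstream, and normalization cancels in ranks).
    """
    g = net.graph if isinstance(net, CoexpressionNetwork) else net
    deg = dict(g.degree)
    btw = nx.betweenness_centrality(g, normalized=False)
    nodes = list(g.nodes)
    return pd.DataFrame(
        {
            "degree": pd.Series(deg, dtype=int),
            "betweenness": pd.Series(btw, dtype=float),
        }
    ).loc[nodes].rename_axis("gene_id")


@dataclass
class NeighborLayers:
    focal: str
    first_layer: set
    second_layer: set
    outside: set


def ego_layers(net, focal: str) -> NeighborLayers:
    """First and second shortest-path layers around a focal gene."""
    g = net.graph if isinstance(net, CoexpressionNetwork) else net
    if focal not in g:
        close = difflib.get_close_matches(str(focal), [str(n) for n in g.nodes], n=5)
        raise KeyError(
            f"focal gene {focal!r} not in network; nearest ids: {close}"
        )
    dist = nx.single_source_shortest_path_length(g, focal)
    first = {v for v, d in dist.items() if d == 1}
    second = {v for v, d in dist.items() if d == 2}
    outside = set(g.nodes) - first - second - {focal}
    return NeighborLayers(focal=focal, first_layer=first, second_layer=second,
                          outside=outside)


def hub_ranking(ct: pd.DataFrame, ann: pd.DataFrame | None = None,
                tf_only: bool = False, nodes=None) -> list[str]:
    """Rank genes by (degree desc, betweenness desc, id asc).

    ``nodes`` restricts the ranking (e.g. to one module's members);
    ``tf_only`` keeps transcription factors per the annotation's ``is_tf``.
    """
    tab = ct if nodes is None else ct.loc[[n for n in nodes if n in ct.index]]
    if tf_only:
        if ann is None:
            raise ValueError("tf_only ranking requires an annotation table")
        tfs = set(ann.index[ann["is_tf"].astype(bool)])
        tab = tab.loc[[g for g in tab.index if g in tfs]]
    order = sorted(
        tab.index, key=lambda g: (-tab.at[g, "degree"], -tab.at[g, "betweenness"], g)
    )
    return order


def write_edge_list(net: CoexpressionNetwork, path, header_lines=()) -> None:
    """Cytoscape-importable TSV: source, target, weight."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("source\ttarget\tweight\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['weight']:.6g}\n")


def write_node_table(
    net: CoexpressionNetwork,
    path,
    partition: ModulePartition | None = None,
    centrality: pd.DataFrame | None = None,
    som_units: pd.Series | None = None,
    ann: pd.DataFrame | None = None,
    header_lines=(),
) -> None:
    """Node attribute TSV: gene, SOM unit, module, centralities, annotation."""
    idx = pd.Index(net.nodes, name="gene_id")
    tab = pd.DataFrame(index=idx)
    if som_units is not None:
        tab["som_unit"] = som_units.reindex(idx)
    if partition is not None:
        tab["module"] = partition.labels.reindex(idx)
    if centrality is not None:
        tab["degree"] = centrality["degree"].reindex(idx)
        tab["betweenness"] = centrality["betweenness"].reindex(idx)
    if ann is not None:
        tab["is_tf"] = ann["is_tf"].reindex(idx)
        tab["description"] = ann["description"].reindex(idx)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        tab.to_csv(fh, sep="\t")
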