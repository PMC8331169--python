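"""Synthetic multi-tissue expression, coexpression modules and benchmark graphs.

Every generator is a pure function of its parameters and a seed, and
records its ground truth so each pipeline stage has a recovery test:

* :func:`simulate_tissue_counts` emulates a multi-tissue bulk RNA-seq
  design — six tissue classes by default (seed, seedling, stem,
  prehaustoria, haustoria, flower) with replicates, negative-binomial
  counts (variance = μ + dispersion·μ²), log-normal per-gene base means,
  log-normal per-sample depth factors, and planted gene clusters jointly
  up-regulated in chosen tissues (e.g. the two invasive stages).
* :func:`simulate_module_expression` emulates hub-centered coexpression
  modules with a one-factor model per module: each gene is
  loading·latent + noise, the hub carrying the largest loading.
* :func:`planted_partition_graph` provides stochastic-block-model
  benchmark graphs for community detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import CountMatrix
from .normalize import NormalizedMatrix

__all__ = [
    "SyntheticTruth",
    "simulate_tissue_counts",
    "simulate_module_expression",
    "planted_partition_graph",
    "DEFAULT_TISSUES",
    "default_tissue_clusters",
]

DEFAULT_TISSUES = ("seed", "seedling", "stem", "prehaustoria", "haustoria", "flower")


def default_tissue_clusters(fold: float = 6.0) -> list[dict]:
    """Twelve planted expression patterns, one per unit of a 6×2 map.

    Real multi-tissue transcriptomes put a distinct dominant pattern in
    every populated map unit, so the default emulates that: the focal
    invasive-stage cluster (up in both prehaustoria and haustoria), one
    tissue-specific cluster per tissue, and five further dual-tissue
    clusters.  The focal cluster is always ``cluster1``.
    """
    cl = [{"size": 60, "up_tissues": ("prehaustoria", "haustoria"), "fold": fold}]
    for t in DEFAULT_TISSUES:
        cl.append({"size": 50, "up_tissues": (t,), "fold": fold})
    for pair in [("seed", "seedling"), ("seedling", "stem"), ("stem", "flower"),
                 ("seed", "flower"), ("stem", "prehaustoria")]:
        cl.append({"size": 50, "up_tissues": pair, "fold": fold})
    return cl


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset."""

    cluster_labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    module_labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    hub_genes: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        idx = self.cluster_labels.index.union(self.module_labels.index)
        return pd.DataFrame(
            {
                "cluster": self.cluster_labels.reindex(idx),
                "module": self.module_labels.reindex(idx),
                "is_hub": pd.Series(True, index=self.hub_genes).reindex(idx, fill_value=False),
            }
        ).rename_axis("gene_id")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance = μ + dispersion·μ²."""
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_tissue_counts(
    n_genes: int = 1000,
    tissue_classes=DEFAULT_TISSUES,
    reps: int = 3,
    clusters=None,
    dispersion: float = 0.1,
    base_log_mean: float = 5.0,
    base_log_sd: float = 1.0,
    depth_log_sd: float = 0.2,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a gene × sample count matrix with planted tissue clusters.

    Per gene, a base mean is drawn log-normal (natural-log mean 5, sd 1,
    so median ≈ 148 counts); genes of each planted cluster are multiplied
    by ``fold`` in that cluster's ``up_tissues``; per-sample depth factors
    are log-normal(0, 0.2) so TMM has signal to estimate; counts are
    negative-binomial with variance μ + dispersion·μ².
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if clusters is None:
        clusters = default_tissue_clusters()
    clusters = [dict(c) for c in clusters]
    if sum(c["size"] for c in clusters) > n_genes:
        raise ValueError("planted cluster sizes exceed n_genes")
    for c in clusters:
        if c.get("fold", 1.0) < 1.0:
            raise ValueError("fold must be >= 1")
        unknown = set(c["up_tissues"]) - set(tissue_classes)
        if unknown:
            raise ValueError(f"unknown up_tissues: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples, classes = [], []
    for t in tissue_classes:
        for r in range(1, reps + 1):
            samples.append(f"{t}_{r}")
            classes.append(t)
    meta = pd.DataFrame(
        {"tissue_class": classes,
         "replicate": [s.rsplit("_", 1)[1] for s in samples]},
        index=pd.Index(samples, name="sample_id"),
    )

    base = np.exp(rng.normal(base_log_mean, base_log_sd, size=n_genes))
    fold_matrix = np.ones((n_genes, len(samples)))
    labels = pd.Series(index=pd.Index(genes), dtype=object)
    pos = 0
    for ci, c in enumerate(clusters, start=1):
        idx = slice(pos, pos + c["size"])
        up_cols = [j for j, t in enumerate(classes) if t in set(c["up_tissues"])]
        fold_matrix[idx, up_cols] = c.get("fold", 1.0)
        labels.iloc[idx] = f"cluster{ci}"
        pos += c["size"]

    depth = np.exp(rng.normal(0.0, depth_log_sd, size=len(samples)))
    mu = base[:, None] * fold_matrix * depth[None, :]
    counts = _nb_draw(rng, mu, dispersion)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta)
    truth = SyntheticTruth(
        cluster_labels=labels.dropna(),
        params={
            "base_means": pd.Series(base, index=genes),
            "depth_factors": pd.Series(depth, index=samples),
            "n_genes": n_genes,
            "tissue_classes": list(tissue_classes),
            "reps": reps,
            "clusters": clusters,
            "dispersion": dispersion,
            "base_log_mean": base_log_mean,
            "base_log_sd": base_log_sd,
            "depth_log_sd": depth_log_sd,
            "seed": seed,
        },
    )
    return cm, truth


def simulate_module_expression(
    n_genes: int = 300,
    modules=(
        {"size": 30, "hub_loading": 1.0, "member_loading": 0.6},
        {"size": 30, "hub_loading": 1.0, "member_loading": 0.6},
        {"size": 30, "hub_loading": 1.0, "member_loading": 0.6},
    ),
    n_samples: int = 30,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[NormalizedMatrix, SyntheticTruth]:
    """Simulate hub-centered coexpression modules with a one-factor model.

    Each module draws a latent standard-normal sample profile; member gene
    values are loading·latent + noise_sd·N(0,1), the designated hub (the
    module's first gene) carrying ``hub_loading`` and members
    ``member_loading``.  Background genes are pure standard-normal noise.
    The result is shaped like a NormalizedMatrix (log-scale expression
    values) so downstream stages consume it directly.
    """
    modules = [dict(m) for m in modules]
    if sum(m["size"] for m in modules) > n_genes:
        raise ValueError("module sizes exceed n_genes")
    for m in modules:
        for key in ("hub_loading", "member_loading"):
            if not 0.0 < m.get(key, 1.0) <= 1.0:
                raise ValueError(f"{key} must be in (0, 1]")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"s{j:02d}" for j in range(n_samples)]
    values = noise_sd * rng.normal(size=(n_genes, n_samples))
    values[sum(m["size"] for m in modules):] = rng.normal(
        size=(n_genes - sum(m["size"] for m in modules), n_samples)
    )

    labels = pd.Series(index=pd.Index(genes), dtype=object)
    hubs = []
    pos = 0
    for mi, m in enumerate(modules, start=1):
        latent = rng.normal(size=n_samples)
        loadings = np.full(m["size"], m["member_loading"])
        loadings[0] = m["hub_loading"]
        values[pos:pos + m["size"]] += loadings[:, None] * latent[None, :]
        labels.iloc[pos:pos + m["size"]] = f"module{mi}"
        hubs.append(genes[pos])
        pos += m["size"]

    nm = NormalizedMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        norm_factors=pd.Series(1.0, index=samples, name="norm_factor"),
        lib_sizes=pd.Series(10**6, index=samples),
        prior=1.0,
        sample_meta=pd.DataFrame(
            {"tissue_class": samples, "replicate": "1"},
            index=pd.Index(samples, name="sample_id"),
        ),
    )
    truth = SyntheticTruth(
        module_labels=labels.dropna(),
        hub_genes=hubs,
        params={
            "n_genes": n_genes,
            "modules": modules,
            "n_samples": n_samples,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    return nm, truth


def planted_partition_graph(
    k: int, size: int, p_in: float, p_out: float, seed: int = 0
) -> tuple[nx.Graph, pd.Series]:
    """Stochastic-block-model benchmark: k blocks of ``size`` nodes.

    Edges are independent Bernoulli draws at p_in within and p_out
    between blocks (0 ≤ p_out < p_in ≤ 1).  Returns the graph and the
    planted block label of each node.
    """
    if not 0.0 <= p_out < p_in <= 1.0:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    g = nx.planted_partition_graph(k, size, p_in, p_out, seed=seed)
    labels = pd.Series({v: v // size for v in g.nodes}, name="block")
    g = nx.Graph(g)  # drop generator bookkeeping attrs, plain simple graph
    return g, labels
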