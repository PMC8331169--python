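"""End-to-end orchestration: counts → normalization → SOM → network → hubs.

Reproduces the full analysis sequence on any count matrix: TMM + log-CPM,
CV filtering, per-gene scaling, PCA and classical MDS, hexagonal SOM
clustering, selection of SOM units, coexpression-network construction,
fast-greedy module partitioning, centrality scoring and hub ranking, the
focal gene's neighbor layers, and per-module term enrichment.  Every
artifact is written as TSV/JSON with a provenance header (seed included),
and a manifest with SHA-256 hashes makes reruns verifiable: identical
config + seed → identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as _annotation
from . import cluster as _cluster
from . import enrich as _enrich
from . import io as _io
from . import network as _network
from . import normalize as _normalize
from . import som as _som

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    counts: str
    meta: str
    outdir: str = "hausnet_out"
    seed: int = 0

    cv_mode: str = "threshold"          # or "quantile"
    cv_value: float = 0.85
    cv_scale: str = "linear"
    scale_by: str = "tissue_mean"       # or "sample"

    som_rows: int = 6
    som_cols: int = 2
    som_epochs: int = 100
    som_alpha: tuple[float, float] = (0.05, 0.01)
    som_neighborhood: str = "bubble"
    selected_units: list[int] = field(default_factory=lambda: [9])

    gcn_method: str = "normal"
    gcn_quantile: float = 0.93
    corr_metric: str = "pearson"        # or "spearman"

    focal_gene: str | None = None
    blast: str | None = None
    tf_list: str | None = None
    gene2term: str | None = None
    evalue_max: float = 1e-5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "som_alpha" in raw:
            raw["som_alpha"] = tuple(raw["som_alpha"])
        return cls(**raw)

    def validate_paths(self) -> None:
        for key in ("counts", "meta", "blast", "tf_list", "gene2term"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {key}={p!r} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df, path: Path, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the artifact manifest (also written).

    Stage failures propagate as exceptions prefixed with the stage name.
    """
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hdr = [f"seed={cfg.seed}"]
    artifacts: dict[str, Path] = {}
    stage = "read"

    def _fail(exc):
        raise RuntimeError(
            f"stage {stage!r} failed: {exc} "
            f"(check the inputs and config keys feeding this stage)"
        ) from exc

    try:
        cm = _io.read_counts(cfg.counts, cfg.meta)

        stage = "normalize"
        nm = _normalize.tmm_normalize(cm)
        _write_tsv(nm.values.rename_axis("gene_id"),
                   outdir / "normalized_logcpm.tsv", hdr)
        artifacts["normalized_logcpm"] = outdir / "normalized_logcpm.tsv"
        factors = pd.DataFrame(
            {"norm_factor": nm.norm_factors, "lib_size": nm.lib_sizes}
        ).rename_axis("sample_id")
        _write_tsv(factors, outdir / "norm_factors.tsv", hdr)
        artifacts["norm_factors"] = outdir / "norm_factors.tsv"

        stage = "filter"
        kept = _cluster.cv_filter(nm, cfg.cv_mode, cfg.cv_value, scale=cfg.cv_scale)
        (outdir / "cv_genes.txt").write_text(
            "".join(f"# {h}\n" for h in hdr) + "\n".join(kept) + "\n"
        )
        artifacts["cv_genes"] = outdir / "cv_genes.txt"
        if len(kept) < max(4, cfg.som_rows * cfg.som_cols):
            raise ValueError(
                f"only {len(kept)} genes pass the CV filter; relax cv_value"
            )

        stage = "scale"
        sm = _cluster.scale_genes(nm, by=cfg.scale_by, genes=kept)

        stage = "ordination"
        pca_res = _cluster.pca(sm)
        _write_tsv(pca_res.scores.rename_axis("gene_id"),
                   outdir / "pca_scores.tsv", hdr)
        artifacts["pca_scores"] = outdir / "pca_scores.tsv"
        loads = pca_res.loadings.copy()
        loads.loc["__variance_fraction__"] = pca_res.variance_fraction
        _write_tsv(loads.rename_axis("column_id"),
                   outdir / "pca_loadings.tsv", hdr)
        artifacts["pca_loadings"] = outdir / "pca_loadings.tsv"
        mds = _cluster.classical_mds(sm.values, k=2)
        _write_tsv(mds.rename_axis("gene_id"), outdir / "mds_coords.tsv", hdr)
        artifacts["mds_coords"] = outdir / "mds_coords.tsv"

        stage = "som"
        fit = _som.som_train(
            sm, cfg.som_rows, cfg.som_cols, epochs=cfg.som_epochs,
            alpha=tuple(cfg.som_alpha), seed=cfg.seed,
            neighborhood=cfg.som_neighborhood,
        )
        _write_tsv(fit.assignment.to_frame().rename_axis("gene_id"),
                   outdir / "som_assignment.tsv", hdr)
        artifacts["som_assignment"] = outdir / "som_assignment.tsv"
        summary = _som.som_summarize(fit, sm)
        summ = summary.means.copy()
        summ["n_genes"] = summary.gene_counts
        _write_tsv(summ, outdir / "som_summary.tsv", hdr)
        artifacts["som_summary"] = outdir / "som_summary.tsv"

        stage = "select"
        selected = _som.select_som_clusters(fit, cfg.selected_units)
        (outdir / "selected_genes.txt").write_text(
            "".join(f"# {h}\n" for h in hdr) + "\n".join(selected) + "\n"
        )
        artifacts["selected_genes"] = outdir / "selected_genes.txt"
        if len(selected) < 3:
            raise ValueError(
                f"selected units {cfg.selected_units} contain only "
                f"{len(selected)} genes; pick different units"
            )

        stage = "annotation"
        ann = None
        tf_ids: list[str] = []
        if cfg.tf_list is not None:
            tf_ids = [
                ln.strip() for ln in Path(cfg.tf_list).read_text().splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
        if cfg.blast is not None:
            ann = _annotation.merge_annotation(
                cfg.blast, nm.gene_ids, evalue_max=cfg.evalue_max, tf_ids=tf_ids
            )
        elif tf_ids:
            ann = _annotation.merge_annotation(
                pd.DataFrame(columns=_annotation.BLAST6_COLUMNS),
                nm.gene_ids, tf_ids=tf_ids,
            )
        if ann is not None:
            _annotation.write_annotation(ann, outdir / "annotation.tsv", hdr)
            artifacts["annotation"] = outdir / "annotation.tsv"

        stage = "network"
        corr_fn = (_network.pearson_matrix if cfg.corr_metric == "pearson"
                   else _network.spearman_matrix)
        corr = corr_fn(_cluster.scale_genes(nm, by="sample", genes=selected))
        net = _network.build_gcn(corr, q=cfg.gcn_quantile, method=cfg.gcn_method)
        rec = net.threshold_record
        net_hdr = hdr + [
            f"method={rec.method} q={rec.quantile} cutoff={rec.cutoff:.6g} "
            f"scale={rec.cutoff_scale} pairs={rec.n_candidate_pairs} "
            f"edges={rec.n_edges}"
        ]
        _network.write_edge_list(net, outdir / "gcn_edges.tsv", net_hdr)
        artifacts["gcn_edges"] = outdir / "gcn_edges.tsv"

        stage = "modules"
        part = _network.fast_greedy_partition(net)
        _write_tsv(part.labels.to_frame().rename_axis("gene_id"),
                   outdir / "modules.tsv",
                   net_hdr + [f"modularity_q={part.modularity_q:.6f}"])
        artifacts["modules"] = outdir / "modules.tsv"

        stage = "centrality"
        cent = _network.centrality_scores(net)
        _write_tsv(cent, outdir / "centrality.tsv", hdr)
        artifacts["centrality"] = outdir / "centrality.tsv"

        _network.write_node_table(
            net, outdir / "gcn_nodes.tsv", partition=part, centrality=cent,
            som_units=fit.assignment, ann=ann, header_lines=net_hdr,
        )
        artifacts["gcn_nodes"] = outdir / "gcn_nodes.tsv"
        import networkx as nx

        nx.write_graphml(net.graph, outdir / "gcn.graphml")
        artifacts["gcn_graphml"] = outdir / "gcn.graphml"

        stage = "ego"
        if cfg.focal_gene is not None:
            layers = _network.ego_layers(net, cfg.focal_gene)
            report = {
                "focal": layers.focal,
                "n_first_layer": len(layers.first_layer),
                "n_second_layer": len(layers.second_layer),
                "first_layer": sorted(layers.first_layer),
                "second_layer": sorted(layers.second_layer),
                "seed": cfg.seed,
            }
            (outdir / "ego_report.json").write_text(
                json.dumps(report, indent=2) + "\n"
            )
            artifacts["ego_report"] = outdir / "ego_report.json"

        stage = "enrich"
        if cfg.gene2term is not None:
            gene2term = _io.read_gene2term(cfg.gene2term)
            universe = set(selected)
            for mod in sorted(part.labels.unique()):
                members = set(part.members(int(mod)))
                if len(members) < 2:
                    continue
                res = _enrich.enrich_terms(members, universe, gene2term)
                name = f"enrichment_module{int(mod)}"
                _write_tsv(res.set_index("term_id"),
                           outdir / f"{name}.tsv", hdr)
                artifacts[name] = outdir / f"{name}.tsv"

        stage = "manifest"
        manifest = {
            "seed": cfg.seed,
            "params": dataclasses.asdict(cfg),
            "artifacts": {
                name: {"path": p.name, "sha256": _sha256(p)}
                for name, p in sorted(artifacts.items())
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        _fail(exc)
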