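"""Best-hit annotation merging from BLAST tabular (outfmt 6) output.

For each query gene, hits with e-value above the threshold are discarded and
the highest-bitscore survivor is kept (ties: smaller e-value, then
lexicographic subject id).  Genes without a qualifying hit get an empty
annotation row.  Transcription-factor status is assigned from a caller-
supplied id list rather than any built-in database.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["merge_annotation", "read_blast_tab", "write_annotation"]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path) -> pd.DataFrame:
    """Parse a 12-column BLAST tabular file; malformed lines are hard errors."""
    rows = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"line {ln}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        parts[0], parts[1], float(parts[2]), int(parts[3]),
                        int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                        int(parts[8]), int(parts[9]), float(parts[10]),
                        float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {ln}: malformed field ({exc})") from None
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


def merge_annotation(
    blast_path,
    genes,
    evalue_max: float = 1e-5,
    tf_ids=(),
    descriptions: dict[str, str] | None = None,
    tair_ids: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One best BLAST hit per gene, filtered at ``evalue_max``.

    Parameters
    ----------
    blast_path
        12-column tabular hit file (or an already-parsed DataFrame).
    genes
        Gene ids to annotate; hits for unlisted queries are logged and
        skipped.
    evalue_max
        Hits with larger e-value are ignored (default 1e-5).
    tf_ids
        Ids of genes to flag as transcription factors.
    descriptions, tair_ids
        Optional subject-id → text maps filled into the output.

    Returns a DataFrame indexed by gene id with columns ``best_hit_id``,
    ``bitscore``, ``evalue``, ``tair_id``, ``description``, ``is_tf``.
    """
    genes = list(genes)
    hits = blast_path if isinstance(blast_path, pd.DataFrame) else read_blast_tab(blast_path)
    known = set(genes)
    unknown = set(hits["qseqid"]) - known
    if unknown:
        logger.warning("skipping hits for %d genes not in gene list", len(unknown))
        hits = hits[hits["qseqid"].isin(known)]
    hits = hits[hits["evalue"] <= evalue_max]
    # deterministic best hit: max bitscore, then min evalue, then subject id
    hits = hits.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = hits.drop_duplicates("qseqid", keep="first").set_index("qseqid")

    tf_set = set(tf_ids)
    descriptions = descriptions or {}
    tair_ids = tair_ids or {}
    records = []
    for g in genes:
        if g in best.index:
            hit = best.loc[g]
            records.append(
                {
                    "best_hit_id": hit["sseqid"],
                    "bitscore": float(hit["bitscore"]),
                    "evalue": float(hit["evalue"]),
                    "tair_id": tair_ids.get(hit["sseqid"], ""),
                    "description": descriptions.get(hit["sseqid"], ""),
                    "is_tf": g in tf_set,
                }
            )
        else:
            records.append(
                {
                    "best_hit_id": "",
                    "bitscore": float("nan"),
                    "evalue": float("nan"),
                    "tair_id": "",
                    "description": "",
                    "is_tf": g in tf_set,
                }
            )
    out = pd.DataFrame(records, index=pd.Index(genes, name="gene_id"))
    return out


def write_annotation(ann: pd.DataFrame, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        ann.to_csv(fh, sep="\t")
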