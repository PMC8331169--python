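"""Reading and writing of count matrices, sample metadata and gene→term maps.

All tabular formats are plain TSV.  A count file has gene ids in the first
column and a header row of sample ids; the companion metadata file maps each
sample id to a ``tissue_class`` and a ``replicate`` label.  Lines starting
with ``#`` are treated as comments (pipeline outputs carry provenance
headers in that form).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "read_counts", "write_counts", "read_gene2term"]


@dataclass
class CountMatrix:
    """Raw nonnegative integer counts, genes × samples, with sample metadata.

    Parameters
    ----------
    counts
        Integer DataFrame indexed by gene id with sample ids as columns.
    sample_meta
        DataFrame indexed by sample id with at least a ``tissue_class``
        column; a ``replicate`` column is added (empty) if missing.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))[0]
                raise ValueError(
                    "non-integer count at gene "
                    f"{self.counts.index[bad[0]]!r}, sample "
                    f"{self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(
                {"tissue_class": self.counts.columns, "replicate": ""},
                index=self.counts.columns,
            )
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        if "tissue_class" not in self.sample_meta.columns:
            raise ValueError("sample metadata must have a 'tissue_class' column")
        if "replicate" not in self.sample_meta.columns:
            self.sample_meta = self.sample_meta.assign(replicate="")
        # align metadata to matrix column order
        self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lib_sizes(self) -> pd.Series:
        """Per-sample library size (column sum of raw counts)."""
        return self.counts.sum(axis=0)

    @property
    def tissue_classes(self) -> pd.Series:
        return self.sample_meta["tissue_class"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def read_counts(path, meta_path=None) -> CountMatrix:
    """Read a gene × sample count TSV (plus optional metadata TSV).

    The first column holds gene ids, the header row sample ids.  Errors are
    raised for duplicate ids, non-integer or negative cells, and samples
    absent from the metadata.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str)
        if "sample_id" not in meta.columns:
            raise ValueError("metadata file must have a 'sample_id' column")
        meta = meta.set_index("sample_id")
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, path, meta_path=None, header_lines=()) -> None:
    """Write a CountMatrix (and optionally its metadata) back to TSV."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        cm.counts.rename_axis("gene_id").to_csv(fh, sep="\t")
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            cm.sample_meta.rename_axis("sample_id").to_csv(fh, sep="\t")


def read_gene2term(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a gene→term mapping for enrichment.

    Two dialects are accepted:

    * GMT-style: ``term_id <TAB> term_name <TAB> gene1 <TAB> gene2 ...``
    * two-column TSV: ``gene_id <TAB> term_id`` (term name = term id)

    Returns ``{term_id: (term_name, frozenset(member genes))}``.
    """
    terms: dict[str, tuple[str, set[str]]] = {}
    two_col = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if two_col is None:
                two_col = len(parts) == 2
            if two_col:
                if len(parts) != 2:
                    raise ValueError(f"line {ln}: expected 2 columns")
                gene, term = parts
                terms.setdefault(term, (term, set()))[1].add(gene)
            else:
                if len(parts) < 3:
                    raise ValueError(f"line {ln}: expected GMT line with >=3 columns")
                term, name, *genes = parts
                terms.setdefault(term, (name, set()))[1].update(g for g in genes if g)
    return {t: (name, frozenset(members)) for t, (name, members) in terms.items()}
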