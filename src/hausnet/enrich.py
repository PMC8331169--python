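"""Offline term over-representation analysis.

For a target gene set of size n drawn from a universe of size N, a term
annotating K universe genes and overlapping the target in k genes gets the
upper-tail hypergeometric probability

    p = Σ_{i=k}^{min(K,n)} C(K,i)·C(N−K,n−i) / C(N,n),

i.e. the chance of an overlap at least as large under random sampling.
Benjamini–Hochberg step-up control is applied across all tested terms.
Only over-representation is tested.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["enrich_terms"]


def enrich_terms(target, universe, gene2term) -> pd.DataFrame:
    """Hypergeometric enrichment of terms in ``target`` against ``universe``.

    Parameters
    ----------
    target, universe
        Gene id collections with ``target ⊆ universe`` (violations are a
        hard error naming the offending gene).
    gene2term
        ``{term_id: (term_name, members)}`` as returned by
        :func:`hausnet.io.read_gene2term`, or ``{term_id: members}``.

    Returns a DataFrame sorted by p-value (ties by term id) with columns
    term_id, term_name, k, K, n, N, p_value, fdr.  Terms with no member in
    the universe are skipped.
    """
    target = set(target)
    universe = set(universe)
    stray = target - universe
    if stray:
        raise ValueError(f"target gene not in universe: {sorted(stray)[0]!r}")
    n, cap_n = len(target), len(universe)

    rows = []
    for term_id in sorted(gene2term):
        entry = gene2term[term_id]
        if isinstance(entry, tuple):
            name, members = entry
        else:
            name, members = term_id, entry
        members = set(members) & universe
        cap_k = len(members)
        if cap_k == 0:
            continue
        k = len(members & target)
        p = float(hypergeom.sf(k - 1, cap_n, cap_k, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "k": k,
                "K": cap_k,
                "n": n,
                "N": cap_n,
                "p_value": min(max(p, 5e-324), 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "fdr"]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return out
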