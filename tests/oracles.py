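"""Independent reference implementations used only to check the package.

Everything here is deliberately written from scratch with different code
paths (explicit loops, manual ranking, exhaustive enumeration) so that the
package and the oracle can only agree by computing the same quantity.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- TMM ----

def _midranks(values):
    """1-based average ranks with midranks for ties (manual, no scipy)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j + 1) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_factor_oracle(obs, ref, m_trim=0.30, a_trim=0.05):
    """Weighted trimmed mean of M, coded directly from the definition."""
    obs = [float(x) for x in obs]
    ref = [float(x) for x in ref]
    n_obs, n_ref = sum(obs), sum(ref)
    m, a, w = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            po, pr = o / n_obs, r / n_ref
            m.append(math.log2(po / pr))
            a.append((math.log2(po) + math.log2(pr)) / 2.0)
            w.append((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    if not m or max(abs(x) for x in m) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = math.floor(n * m_trim) + 1, n - math.floor(n * m_trim)
    lo_a, hi_a = math.floor(n * a_trim) + 1, n - math.floor(n * a_trim)
    rm, ra = _midranks(m), _midranks(a)
    num = den = 0.0
    kept = 0
    for i in range(n):
        if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
            num += m[i] / w[i]
            den += 1.0 / w[i]
            kept += 1
    if kept == 0:
        num = sum(mi / wi for mi, wi in zip(m, w))
        den = sum(1.0 / wi for wi in w)
    return 2.0 ** (num / den)


def tmm_factors_oracle(counts: np.ndarray, m_trim=0.30, a_trim=0.05):
    """All-sample TMM factors: reference choice, pair factors, recentering."""
    lib = counts.sum(axis=0)
    uq = [np.quantile(counts[:, j], 0.75) / lib[j] for j in range(counts.shape[1])]
    ref = min(range(len(uq)), key=lambda j: abs(uq[j] - sum(uq) / len(uq)))
    f = [
        tmm_factor_oracle(counts[:, j], counts[:, ref], m_trim, a_trim)
        for j in range(counts.shape[1])
    ]
    g = math.exp(sum(math.log(x) for x in f) / len(f))
    return [x / g for x in f], ref


# -------------------------------------------------------- betweenness ----

def betweenness_oracle(graph):
    """Betweenness by exhaustive enumeration of all shortest paths.

    For every unordered pair (s, t) the full set of shortest paths is
    enumerated on the BFS distance layers; each interior node of each
    path receives (its path share) of the pair's unit dependency.
    """
    import networkx as nx

    nodes = list(graph.nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            dist = nx.shortest_path_length(graph, s)
        except Exception:
            continue
        if t not in dist:
            continue

        paths = []

        def extend(path):
            last = path[-1]
            if last == t:
                paths.append(path)
                return
            for nb in graph.neighbors(last):
                if dist.get(nb) == dist[last] + 1 and dist[nb] <= dist[t]:
                    extend(path + [nb])

        extend([s])
        share = 1.0 / len(paths)
        for p in paths:
            for v in p[1:-1]:
                score[v] += share
    return score


# --------------------------------------------------------- modularity ----

def set_partitions(items):
    """All partitions of a list (restricted-growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def modularity_oracle(graph, blocks):
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for block in blocks:
        bs = set(block)
        mc = sum(1 for u, v in graph.edges if u in bs and v in bs)
        dc = sum(graph.degree(v) for v in bs)
        q += mc / m - (dc / (2 * m)) ** 2
    return q


def max_modularity_oracle(graph):
    """Exhaustive maximum-modularity search (graphs of <= ~10 nodes)."""
    best_q, best_blocks = -1.0, None
    for blocks in set_partitions(list(graph.nodes)):
        q = modularity_oracle(graph, blocks)
        if q > best_q:
            best_q, best_blocks = q, blocks
    return best_q, best_blocks


# ----------------------------------------------------------- best hit ----

def best_hits_oracle(rows, genes, evalue_max):
    """Brute-force per-gene scan for the best qualifying BLAST hit.

    rows: iterables (qseqid, sseqid, evalue, bitscore).  Ties broken by
    smaller evalue, then lexicographic subject id.
    """
    best = {}
    for q, s, e, b in rows:
        if q not in genes or e > evalue_max:
            continue
        cur = best.get(q)
        cand = (-b, e, s)
        if cur is None or cand < cur:
            best[q] = cand
    return {q: (s, e, -nb) for q, (nb, e, s) in best.items()}
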