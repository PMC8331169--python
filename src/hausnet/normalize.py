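"""Between-sample count normalization by the trimmed mean of M-values (TMM).

TMM corrects for composition bias between RNA-seq libraries: for each sample
against a reference sample, per-gene log expression ratios

    M_g = log2( (x_g / N) / (r_g / N_ref) )

and log mean abundances

    A_g = ( log2(x_g / N) + log2(r_g / N_ref) ) / 2

are computed over genes positive in both samples; M is trimmed two-sided by
30% and A by 5%, and the scaling factor is 2 raised to the precision-weighted
mean of the surviving M values, with weights from the delta-method variance
of a log ratio of counts.  Factors are recentered to geometric mean 1.
Downstream stages consume log2 counts-per-million computed with these
factors and a prior count of 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["NormalizedMatrix", "tmm_normalize", "tmm_pair_factor"]


@dataclass
class NormalizedMatrix:
    """log2-CPM values with the normalization factors that produced them."""

    values: pd.DataFrame        # genes × samples, log2(CPM + prior)
    norm_factors: pd.Series     # per-sample positive floats, geo-mean 1
    lib_sizes: pd.Series        # per-sample raw library sizes
    prior: float = 1.0
    sample_meta: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissue_classes(self) -> pd.Series | None:
        if self.sample_meta is None:
            return None
        return self.sample_meta["tissue_class"]


def tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float | None = None,
    lib_ref: float | None = None,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> float:
    """TMM scaling factor of one sample against a reference sample.

    Only genes positive in both samples enter; M-values are trimmed by
    ``m_trim`` and A-values by ``a_trim`` (two-sided, rank-based with
    midranks for ties), and the factor is 2**(precision-weighted trimmed
    mean of M).  Returns 1.0 when the samples are proportional.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n_obs = float(obs.sum()) if lib_obs is None else float(lib_obs)
    n_ref = float(ref.sum()) if lib_ref is None else float(lib_ref)
    if n_obs <= 0 or n_ref <= 0:
        raise ValueError("library sizes must be positive")

    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("no gene is positive in both samples")
    o, r = obs[pos], ref[pos]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = (np.log2(o / n_obs) + np.log2(r / n_ref)) / 2.0
    # delta-method variance of M for binomial counts
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = m.size
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        logger.warning(
            "too few genes (%d) to trim at m_trim=%.2f a_trim=%.2f; "
            "using untrimmed weighted mean",
            n, m_trim, a_trim,
        )
        keep = np.ones(n, dtype=bool)
    # guard zero weights (can only arise with lib-size-equal counts)
    wk = np.where(w[keep] > 0, w[keep], np.finfo(float).tiny)
    f = np.sum(m[keep] / wk) / np.sum(1.0 / wk)
    return float(2.0 ** f)


def _choose_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Reference sample: upper-quartile rate closest to the mean upper quartile."""
    uq = np.quantile(counts, 0.75, axis=0) / lib_sizes
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_normalize(
    cm,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
    prior: float = 1.0,
) -> NormalizedMatrix:
    """TMM-normalize a CountMatrix and return log2-CPM values.

    Genes with zero counts in every sample are dropped (logged) before
    factor estimation.  A sample with an all-zero column is an error.
    The returned values are ``log2(1e6 * x / (lib_size * factor) + prior)``,
    so a zero count maps exactly to ``log2(prior)``.
    """
    counts = cm.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")

    nonzero = counts.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d genes with zero counts in all samples", n_dropped)
        counts = counts.loc[nonzero]

    arr = counts.to_numpy(dtype=float)
    libv = lib.to_numpy(dtype=float)
    ref = _choose_reference(arr, libv)
    factors = np.array(
        [
            tmm_pair_factor(arr[:, j], arr[:, ref], libv[j], libv[ref], m_trim, a_trim)
            for j in range(arr.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))

    eff = libv * factors
    values = np.log2(1e6 * arr / eff[np.newaxis, :] + prior)
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=counts.index, columns=counts.columns),
        norm_factors=pd.Series(factors, index=counts.columns, name="norm_factor"),
        lib_sizes=lib,
        prior=prior,
        sample_meta=cm.sample_meta,
    )
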