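"""Gene filtering, scaling and ordination ahead of map clustering.

The variability filter keeps genes whose coefficient of variation
(sd / mean, sample sd with n−1) exceeds either a fixed threshold or a
quantile of all gene CVs; CV is computed on the linear CPM scale by
default, where the conventional cutoffs (e.g. 0.85) live.  Scaling
produces per-gene z-scores over samples or over tissue-class means, the
representation fed to PCA, classical MDS, the SOM and the coexpression
networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ScaledMatrix", "PcaResult", "cv_filter", "scale_genes", "pca", "classical_mds"]


@dataclass
class ScaledMatrix:
    """Per-gene z-scores; rows have mean 0 and sample sd 1."""

    values: pd.DataFrame  # genes × columns (samples or tissue-class means)
    tissue_classes: pd.Series | None = None  # per-column class labels

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PcaResult:
    scores: pd.DataFrame            # genes × components
    loadings: pd.DataFrame          # columns × components
    variance_fraction: pd.Series    # per component, sums to 1


def gene_cv(nm, scale: str = "linear") -> pd.Series:
    """Coefficient of variation per gene (sd/mean, ddof=1).

    ``scale='linear'`` un-logs the stored log2-CPM values back to CPM;
    ``scale='log'`` uses them as stored.  Genes with nonpositive mean get
    NaN (excluded by the filter).
    """
    vals = nm.values
    if scale == "linear":
        vals = np.power(2.0, vals) - nm.prior
        vals = vals.clip(lower=0.0)
    elif scale != "log":
        raise ValueError("scale must be 'linear' or 'log'")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    cv = sd / mean
    cv[mean <= 0] = np.nan
    return cv


def cv_filter(nm, mode: str, value: float, scale: str = "linear") -> list[str]:
    """Select variable genes by coefficient of variation.

    ``mode='threshold'`` keeps genes with CV > value; ``mode='quantile'``
    keeps genes strictly above the value-quantile of all computed CVs
    (value must lie in [0, 1]).
    """
    cv = gene_cv(nm, scale=scale).dropna()
    if mode == "threshold":
        cut = float(value)
    elif mode == "quantile":
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"quantile must be in [0, 1], got {value}")
        cut = float(np.quantile(cv.to_numpy(), value))
    else:
        raise ValueError("mode must be 'threshold' or 'quantile'")
    kept = cv.index[cv > cut]
    return list(kept)


def scale_genes(nm, by: str = "sample", genes=None) -> ScaledMatrix:
    """Z-score each gene across samples or across tissue-class means.

    ``by='tissue_mean'`` first averages replicates within each tissue
    class (column order = first appearance in the metadata), then
    z-scores.  Zero-variance genes are dropped with a logged count.
    """
    vals = nm.values if genes is None else nm.values.loc[list(genes)]
    classes = None
    if by == "tissue_mean":
        tc = nm.tissue_classes
        if tc is None:
            raise ValueError("tissue_mean scaling requires sample metadata")
        order = list(dict.fromkeys(tc))
        vals = vals.T.groupby(tc).mean().T[order]
        classes = pd.Series(order, index=vals.columns)
    elif by == "sample":
        if nm.tissue_classes is not None:
            classes = nm.tissue_classes.reindex(vals.columns)
    else:
        raise ValueError("by must be 'sample' or 'tissue_mean'")

    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance genes before scaling", n_dropped)
    z = vals.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return ScaledMatrix(values=z, tissue_classes=classes)


def pca(sm: ScaledMatrix) -> PcaResult:
    """Principal components with genes as observations.

    Columns are centered and decomposed by SVD.  Sign convention: the
    largest-magnitude entry of each loading vector is positive.  Scores
    reproduce the centered data exactly under the loadings.
    """
    x = sm.values.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 columns")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if s[0] <= 1e-12 * max(xc.shape):
        raise ValueError("degenerate (rank-0) input: all rows identical")
    # sign convention
    for j in range(vt.shape[0]):
        k = np.argmax(np.abs(vt[j]))
        if vt[j, k] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u * s
    var = s ** 2
    frac = var / var.sum()
    comps = [f"PC{i+1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=sm.values.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=sm.values.columns, columns=comps),
        variance_fraction=pd.Series(frac, index=comps, name="variance_fraction"),
    )


def classical_mds(data, k: int = 2, is_distance: bool | None = None) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling.

    ``data`` is either a point configuration (rows = items) or a symmetric
    distance matrix with zero diagonal; when points are given, Euclidean
    distances are computed.  Coordinates come from the eigendecomposition
    of the double-centered squared-distance matrix, components ordered by
    decreasing eigenvalue; only positive eigenvalues contribute.
    """
    if isinstance(data, pd.DataFrame):
        index = data.index
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        index = pd.RangeIndex(arr.shape[0])
    if is_distance is None:
        is_distance = (
            arr.ndim == 2
            and arr.shape[0] == arr.shape[1]
            and np.allclose(np.diag(arr), 0.0)
            and np.allclose(arr, arr.T, atol=1e-8)
        )
    if is_distance:
        d = arr
        if d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.max(np.abs(d - d.T)) > 1e-8:
            raise ValueError("distance matrix is asymmetric beyond 1e-8")
        if (d < -1e-12).any():
            raise ValueError("distances must be nonnegative")
    else:
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(arr))

    n = d.shape[0]
    d2 = d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(k, n)
    coords = np.zeros((n, k))
    for i in range(k):
        if evals[i] > 1e-12:
            coords[:, i] = evecs[:, i] * np.sqrt(evals[i])
    return pd.DataFrame(coords, index=index, columns=[f"MDS{i+1}" for i in range(k)])
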