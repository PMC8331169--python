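import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hausnet.cluster import (ScaledMatrix, classical_mds, cv_filter, gene_cv,
                             pca, scale_genes)
from hausnet.normalize import NormalizedMatrix


def _nm(values, classes=None, prior=1.0):
    values = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(np.asarray(values).shape[0])],
        columns=[f"s{j}" for j in range(np.asarray(values).shape[1])],
    )
    meta = None
    if classes is not None:
        meta = pd.DataFrame(
            {"tissue_class": classes, "replicate": "1"},
            index=pd.Index(values.columns, name="sample_id"),
        )
    return NormalizedMatrix(
        values=values,
        norm_factors=pd.Series(1.0, index=values.columns),
        lib_sizes=pd.Series(10**6, index=values.columns),
        prior=prior,
        sample_meta=meta,
    )


# ------------------------------------------------------------ CV filter ----

def test_constant_gene_excluded():
    nm = _nm([[3.0, 3.0, 3.0], [1.0, 5.0, 9.0]])
    kept = cv_filter(nm, "threshold", 0.85, scale="log")
    assert "g0" not in kept


def test_quantile_median_split_exact():
    rng = np.random.default_rng(0)
    vals = rng.normal(5, 1, size=(10, 6)) * np.linspace(1, 4, 10)[:, None]
    nm = _nm(vals)
    cvs = gene_cv(nm, scale="log")
    assert cvs.nunique() == 10  # strictly distinct
    kept = cv_filter(nm, "quantile", 0.5, scale="log")
    assert len(kept) == 5
    assert set(kept) == set(cvs.nlargest(5).index)


def test_threshold_matches_direct_recomputation():
    rng = np.random.default_rng(42)
    vals = np.abs(rng.normal(4, 2, size=(50, 8))) + 0.1
    nm = _nm(vals)
    kept = cv_filter(nm, "threshold", 0.3, scale="log")
    expected = []
    for i, g in enumerate(nm.gene_ids):
        row = vals[i]
        cv = row.std(ddof=1) / row.mean()
        if row.mean() > 0 and cv > 0.3:
            expected.append(g)
    assert kept == expected


def test_quantile_out_of_range_errors():
    nm = _nm(np.random.default_rng(1).normal(5, 1, (5, 4)))
    with pytest.raises(ValueError, match="quantile"):
        cv_filter(nm, "quantile", 1.5)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(factor=st.floats(min_value=0.1, max_value=50.0))
def test_cv_invariant_to_global_rescale(factor):
    """CV (linear scale) is unchanged when the count scale changes globally."""
    rng = np.random.default_rng(9)
    cpm = np.abs(rng.normal(40, 25, size=(30, 6))) + 1.0
    nm1 = _nm(np.log2(cpm + 1.0))
    nm2 = _nm(np.log2(cpm * factor + 1.0))
    cv1 = gene_cv(nm1, scale="linear")
    cv2 = gene_cv(nm2, scale="linear")
    assert np.allclose(cv1, cv2, rtol=1e-9)


# --------------------------------------------------------------- scaling ----

def test_zscore_symmetric_case():
    nm = _nm([[1.0, 2.0, 3.0]])
    sm = scale_genes(nm, by="sample")
    assert np.allclose(sm.values.iloc[0], [-1.0, 0.0, 1.0])


def test_zero_variance_gene_dropped(caplog):
    nm = _nm([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
    with caplog.at_level("INFO"):
        sm = scale_genes(nm, by="sample")
    assert list(sm.values.index) == ["g1"]
    assert "zero-variance" in caplog.text


def test_scaled_rows_have_mean0_sd1():
    rng = np.random.default_rng(3)
    sm = scale_genes(_nm(rng.normal(5, 2, (20, 8))), by="sample")
    assert np.allclose(sm.values.mean(axis=1), 0.0, atol=1e-9)
    assert np.allclose(sm.values.std(axis=1, ddof=1), 1.0, atol=1e-9)


def test_tissue_mean_equals_collapsed_path():
    """With equal replicates, tissue_mean scaling = scaling collapsed data."""
    rng = np.random.default_rng(8)
    base = rng.normal(6, 2, size=(15, 3))
    vals = np.repeat(base, 2, axis=1)  # two identical replicates per class
    nm = _nm(vals, classes=["a", "a", "b", "b", "c", "c"])
    sm = scale_genes(nm, by="tissue_mean")
    collapsed = _nm(base, classes=["a", "b", "c"])
    sm2 = scale_genes(collapsed, by="sample")
    assert np.allclose(sm.values.to_numpy(), sm2.values.to_numpy())


# ------------------------------------------------------------------- PCA ----

def _sm(values):
    return ScaledMatrix(values=pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(np.asarray(values).shape[0])],
        columns=[f"c{j}" for j in range(np.asarray(values).shape[1])],
    ))


def test_rank1_input_puts_all_variance_on_pc1():
    x = np.outer(np.arange(1.0, 7.0), [1.0, 2.0])
    res = pca(_sm(x))
    assert abs(res.variance_fraction.iloc[0] - 1.0) < 1e-9


def test_variance_fractions_sum_to_one_and_reconstruction():
    rng = np.random.default_rng(12)
    x = rng.normal(size=(40, 5))
    res = pca(_sm(x))
    assert abs(res.variance_fraction.sum() - 1.0) < 1e-9
    assert (np.diff(res.variance_fraction) <= 1e-12).all()
    xc = x - x.mean(axis=0)
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    assert np.allclose(recon, xc, atol=1e-8)
    # sign convention: largest-|.| loading entry positive
    for col in res.loadings.columns:
        v = res.loadings[col].to_numpy()
        assert v[np.argmax(np.abs(v))] > 0


def test_pca_matches_eigendecomposition_oracle():
    """Scores/loadings equal those from the covariance eigenproblem."""
    rng = np.random.default_rng(23)
    x = rng.normal(size=(30, 4))
    res = pca(_sm(x))
    xc = x - x.mean(axis=0)
    evals, evecs = np.linalg.eigh(xc.T @ xc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    assert np.allclose(res.variance_fraction, evals / evals.sum(), atol=1e-9)
    for j in range(4):
        dot = abs(np.dot(res.loadings.iloc[:, j], evecs[:, j]))
        assert abs(dot - 1.0) < 1e-8  # same axis up to sign


def test_degenerate_input_errors():
    with pytest.raises(ValueError, match="degenerate"):
        pca(_sm(np.ones((5, 3))))


# ------------------------------------------------------------------- MDS ----

def test_identical_points_coincide():
    x = np.array([[1.0, 2.0], [1.0, 2.0], [4.0, 0.0]])
    coords = classical_mds(x, k=2)
    assert np.allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)


def test_equilateral_triangle_distances_recovered():
    d = np.ones((3, 3)) - np.eye(3)
    coords = classical_mds(d, k=2, is_distance=True).to_numpy()
    from scipy.spatial.distance import pdist

    assert np.allclose(pdist(coords), 1.0, atol=1e-6)


def test_euclidean_distances_preserved_at_intrinsic_dimension():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(12, 3))
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(x))
    coords = classical_mds(d, k=3, is_distance=True).to_numpy()
    assert np.allclose(pdist(coords), pdist(x), atol=1e-6)


def test_asymmetric_matrix_errors():
    d = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="asymmetric"):
        classical_mds(d, is_distance=True)


def test_mds_reproduces_pca_scores():
    """Classical scaling of Euclidean distances = PCA up to sign."""
    rng = np.random.default_rng(17)
    x = rng.normal(size=(25, 4))
    res = pca(_sm(x))
    coords = classical_mds(x - x.mean(axis=0), k=2).to_numpy()
    scores = res.scores.to_numpy()[:, :2]
    for j in range(2):
        err = min(
            np.abs(coords[:, j] - scores[:, j]).max(),
            np.abs(coords[:, j] + scores[:, j]).max(),
        )
        assert err < 1e-6


def test_mds_agrees_with_skbio_pcoa():
    import skbio

    rng = np.random.default_rng(29)
    x = rng.normal(size=(10, 3))
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(x))
    ours = classical_mds(d, k=2, is_distance=True).to_numpy()
    ref = skbio.stats.ordination.pcoa(
        skbio.DistanceMatrix(d), number_of_dimensions=2
    ).samples.to_numpy()
    for j in range(2):
        err = min(
            np.abs(ours[:, j] - ref[:, j]).max(),
            np.abs(ours[:, j] + ref[:, j]).max(),
        )
        assert err < 1e-6
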