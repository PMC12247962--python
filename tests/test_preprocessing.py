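"""Arcsinh transform exactness and the scRNA-seq preprocessing chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytogpnet.data import CellMatrix, ParameterError
from cytogpnet.preprocessing import (
    PreprocessConfig,
    arcsinh_transform,
    inverse_arcsinh,
    preprocess_scrnaseq,
    select_hvg,
)


def test_arcsinh_matches_closed_form():
    # y = ln(u + sqrt(u^2 + 1)) with u = x / c
    x = np.array([[0.0, 5.0, -5.0, 123.4, 1e6]])
    for c in (5.0, 150.0, 1.0):
        u = x / c
        expected = np.log(u + np.sqrt(u**2 + 1))
        np.testing.assert_allclose(arcsinh_transform(x, c), expected, atol=1e-10)
    # the worked value: x = 5, c = 5 -> ln(1 + sqrt 2)
    assert arcsinh_transform(np.array([[5.0]]), 5.0)[0, 0] == pytest.approx(
        0.881374, abs=1e-6
    )
    assert arcsinh_transform(np.zeros((1, 1)), 7.0)[0, 0] == 0.0


def test_mode_default_cofactors():
    assert PreprocessConfig(mode="cytof").cofactor == 5.0
    assert PreprocessConfig(mode="flow").cofactor == 150.0
    with pytest.raises(ParameterError):
        arcsinh_transform(np.ones((2, 2)), -1.0)


def test_arcsinh_preserves_cellmatrix_metadata():
    cm = CellMatrix(np.arange(6, dtype=float).reshape(3, 2), ["a", "b"], "S", 2)
    out = arcsinh_transform(cm, 5.0)
    assert isinstance(out, CellMatrix)
    assert out.marker_names == ["a", "b"] and out.timepoint == 2


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=20),
    st.sampled_from([5.0, 150.0]),
)
def test_arcsinh_odd_monotone_invertible(xs, c):
    x = np.array(xs)
    y = arcsinh_transform(x, c)
    np.testing.assert_allclose(arcsinh_transform(-x, c), -y, atol=1e-12)
    order = np.argsort(x)
    assert (np.diff(y[order]) >= 0).all()
    back = inverse_arcsinh(y, c)
    np.testing.assert_allclose(back, x, rtol=1e-10, atol=1e-10)


def test_select_hvg_picks_high_variance_gene():
    # 4 x 3 toy: gene 2 has by far the largest variance (hand-computed)
    X = np.array(
        [[1.0, 1.0, 0.0], [1.0, 1.0, 10.0], [1.0, 1.0, 0.0], [1.0, 1.0, 10.0]]
    )
    assert X.var(axis=0).tolist() == [0.0, 0.0, 25.0]
    assert select_hvg(X, 1).tolist() == [2]
    assert select_hvg(X, 3).tolist() == [0, 1, 2]
    # constant matrix: ties break toward the lowest index
    assert select_hvg(np.ones((5, 4)), 2).tolist() == [0, 1]
    with pytest.raises(ParameterError):
        select_hvg(X, 4)


def test_scrnaseq_gene_filter_boundary():
    rng = np.random.default_rng(0)
    n_cells = 40
    counts = rng.poisson(5.0, size=(n_cells, 30)).astype(float)
    counts[counts == 0] = 1  # every gene detected everywhere
    counts[:, 3] = 0
    counts[:9, 3] = 7  # detected in exactly 9 cells -> filtered at threshold 10
    counts[:, 4] = 0
    counts[:10, 4] = 7  # exactly 10 cells -> kept
    cfg = PreprocessConfig(mode="scrnaseq", n_hvg=29)
    out = preprocess_scrnaseq(counts, cfg, gene_names=[f"g{j}" for j in range(30)])
    assert "g3" not in out.marker_names  # 9 cells < threshold 10
    assert "g4" in out.marker_names  # exactly 10 cells passes
    assert out.values.shape == (n_cells, 29)


def test_scrnaseq_depth_normalization_and_log1p():
    rng = np.random.default_rng(1)
    counts = rng.poisson(8.0, size=(25, 15)).astype(float) + 1  # no zero totals
    cfg = PreprocessConfig(mode="scrnaseq", min_cells_per_gene=1, n_hvg=15)
    out = preprocess_scrnaseq(counts, cfg)
    # undo log1p: per-cell sums must equal the target depth exactly
    depth = np.expm1(out.values).sum(axis=1)
    np.testing.assert_allclose(depth, 10_000.0, rtol=1e-6)
    # a zero count maps to log1p(0) = 0
    counts2 = counts.copy()
    counts2[0, 0] = 0
    out2 = preprocess_scrnaseq(counts2, cfg)
    assert out2.values[0, 0] == 0.0


def test_scrnaseq_zero_total_cell_raises():
    counts = np.ones((5, 8))
    counts[2, :] = 0
    with pytest.raises(ParameterError, match="zero total"):
        preprocess_scrnaseq(
            counts, PreprocessConfig(mode="scrnaseq", min_cells_per_gene=1, n_hvg=4)
        )


def test_scrnaseq_row_permutation_equivariance():
    rng = np.random.default_rng(2)
    counts = rng.poisson(6.0, size=(30, 12)).astype(float) + 1
    cfg = PreprocessConfig(mode="scrnaseq", min_cells_per_gene=1, n_hvg=6)
    base = preprocess_scrnaseq(counts, cfg)
    perm = rng.permutation(30)
    shuffled = preprocess_scrnaseq(counts[perm], cfg)
    np.testing.assert_allclose(shuffled.values, base.values[perm], atol=1e-12)


def test_scrnaseq_matches_scanpy_pipeline():
    """Cross-check the chain against scanpy's normalize_total + log1p."""
    import anndata as ad
    import scanpy as sc

    rng = np.random.default_rng(3)
    counts = rng.poisson(4.0, size=(50, 20)).astype(float)
    counts[:, rng.integers(0, 20, 3)] += 1
    counts += (counts.sum(axis=1, keepdims=True) == 0)  # avoid zero totals
    cfg = PreprocessConfig(mode="scrnaseq", min_cells_per_gene=1, n_hvg=20)
    ours = preprocess_scrnaseq(counts, cfg)

    adata = ad.AnnData(counts.copy())
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    np.testing.assert_allclose(ours.values, adata.X, rtol=1e-8)
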