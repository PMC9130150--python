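"""Tests for housekeeping and conditional-quantile normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from immsig import ExpressionMatrix, RAW_COUNTS, cqn_normalize, normalize_housekeeping


def counts_matrix(values, genes, samples, gc=None, length=None):
    frame = pd.DataFrame(np.asarray(values, float), index=genes, columns=samples)
    kw = {}
    if gc is not None:
        kw["gene_gc"] = pd.Series(gc, index=genes, dtype=float)
    if length is not None:
        kw["gene_length"] = pd.Series(length, index=genes, dtype=float)
    return ExpressionMatrix(frame, value_scale=RAW_COUNTS, **kw)


# --- housekeeping ----------------------------------------------------------


def test_hand_computed_scale_factors():
    """Two samples whose housekeeping geometric means are 100 and 400: the
    grand geometric mean is 200, so scale factors are 2 and 0.5 and target
    counts 10 / 40 normalize to the identical value log2(20.5)."""
    expr = counts_matrix(
        [[100, 400], [100, 400], [10, 40]], ["HK1", "HK2", "T"], ["s1", "s2"]
    )
    out = normalize_housekeeping(expr, ["HK1", "HK2"], pseudocount=0.5)
    t = out.values.loc["T"]
    assert t["s1"] == pytest.approx(t["s2"], abs=1e-12)
    assert t["s1"] == pytest.approx(np.log2(20.5), abs=1e-12)


def test_pure_library_size_columns_become_identical():
    rng = np.random.default_rng(0)
    base = rng.integers(10, 1000, size=30).astype(float)
    values = np.column_stack([base, base * 3.0, base * 0.5])
    genes = [f"g{i}" for i in range(30)]
    expr = counts_matrix(values, genes, ["a", "b", "c"])
    out = normalize_housekeeping(expr, genes[:5])
    np.testing.assert_allclose(out.values["a"], out.values["b"], rtol=1e-10)
    np.testing.assert_allclose(out.values["a"], out.values["c"], rtol=1e-10)


def test_housekeeping_geometric_means_equalized(default_cohort):
    hk = default_cohort.truth["housekeeping_genes"]
    out = normalize_housekeeping(default_cohort.expression, hk)
    # on the log2 scale the housekeeping mean of 2^x - pseudocount is equal
    linear = np.exp2(out.values.loc[hk].to_numpy()) - 0.5
    gm = np.exp(np.log(linear).mean(axis=0))
    assert np.ptp(gm) < 1e-6 * gm.mean()


def test_named_housekeeping_panel_accepted():
    genes = ["B2M", "GAPDH", "POLR2A", "UBC", "YWHAZ", "TARGET"]
    rng = np.random.default_rng(1)
    expr = counts_matrix(rng.integers(50, 500, size=(6, 4)), genes, list("wxyz"))
    out = normalize_housekeeping(expr, ["B2M", "GAPDH", "POLR2A", "UBC", "YWHAZ"])
    assert out.value_scale == "log2_normalized"
    assert out.values.shape == (6, 4)


def test_housekeeping_set_semantics(default_cohort):
    hk = default_cohort.truth["housekeeping_genes"]
    a = normalize_housekeeping(default_cohort.expression, hk)
    b = normalize_housekeeping(default_cohort.expression, hk[::-1] + hk[:1])
    pd.testing.assert_frame_equal(a.values, b.values)


def test_missing_housekeeping_gene_named_in_error():
    expr = counts_matrix([[1, 2], [3, 4]], ["g1", "g2"], ["a", "b"])
    with pytest.raises(ValueError, match="NOPE"):
        normalize_housekeeping(expr, ["g1", "NOPE"])


def test_all_zero_housekeeping_sample_identified():
    expr = counts_matrix([[0, 5], [0, 7], [3, 4]], ["h1", "h2", "t"], ["bad", "ok"])
    with pytest.raises(ValueError, match="bad"):
        normalize_housekeeping(expr, ["h1", "h2"])


@given(st.permutations(list(range(5))))
def test_housekeeping_permutation_equivariance(perm):
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(12)]
    samples = [f"s{i}" for i in range(5)]
    values = rng.integers(20, 800, size=(12, 5)).astype(float)
    expr = counts_matrix(values, genes, samples)
    out = normalize_housekeeping(expr, genes[:3])
    shuffled = ExpressionMatrix(
        expr.values.iloc[::-1, list(perm)].copy(), value_scale=RAW_COUNTS
    )
    out_shuffled = normalize_housekeeping(shuffled, genes[:3])
    pd.testing.assert_frame_equal(
        out.values.iloc[::-1, list(perm)], out_shuffled.values
    )


# --- conditional quantile normalization ------------------------------------


def _biased_counts(seed, n_genes=1000, n_samples=6, gc_amplitude=0.0,
                   len_amplitude=0.0, base_sd=0.3):
    """Poisson counts with a controlled monotone GC / length log2 offset."""
    rng = np.random.default_rng(seed)
    gc = rng.uniform(0.0, 1.0, n_genes)
    length = np.exp(rng.uniform(np.log(500), np.log(10000), n_genes))
    base = rng.normal(8.0, base_sd, n_genes)
    u_len = (np.log10(length) - np.log10(500)) / (np.log10(10000) - np.log10(500))
    log2_mu = (
        base[:, None]
        + gc_amplitude * (gc - 0.5)[:, None]
        + len_amplitude * (u_len - 0.5)[:, None]
        + rng.normal(0, 0.05, (n_genes, n_samples))
    )
    counts = rng.poisson(np.exp2(log2_mu))
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return counts_matrix(counts, genes, samples, gc=gc, length=length), gc


def _log2_cpm(expr):
    lib = expr.values.sum(axis=0).to_numpy(float)
    return np.log2((expr.values.to_numpy(float) + 0.5) / lib[None, :] * 1e6)


def _gc_slope(matrix, gc):
    mean_expr = matrix.mean(axis=1)
    return np.polyfit(gc, mean_expr, 1)[0]


def test_cqn_without_bias_returns_log2_cpm():
    expr, _ = _biased_counts(seed=0)
    out = cqn_normalize(expr)
    diff = np.abs(out.values.to_numpy() - _log2_cpm(expr))
    assert diff.mean() < 0.1


@pytest.mark.parametrize("seed", range(10))
def test_cqn_removes_injected_gc_bias_across_seeds(seed):
    """A 2-log2-unit monotone GC bias must shrink by >= 90% in regression
    slope after normalization, for every replicate simulation."""
    expr, gc = _biased_counts(seed=seed, gc_amplitude=2.0)
    pre = _gc_slope(_log2_cpm(expr), gc)
    post = _gc_slope(cqn_normalize(expr).values.to_numpy(), gc)
    assert abs(post) < 0.1 * abs(pre)


def test_cqn_removes_length_bias():
    expr, _ = _biased_counts(seed=3, len_amplitude=2.0)
    loglen = np.log10(expr.gene_length.to_numpy())
    pre = np.polyfit(loglen, _log2_cpm(expr).mean(axis=1), 1)[0]
    post = np.polyfit(loglen, cqn_normalize(expr).values.to_numpy().mean(axis=1), 1)[0]
    assert abs(post) < 0.1 * abs(pre)


def test_cqn_library_size_doubling_invariance():
    expr, _ = _biased_counts(seed=5, gc_amplitude=1.0)
    out = cqn_normalize(expr).values
    doubled_values = expr.values.copy()
    doubled_values["s0"] = doubled_values["s0"] * 2
    doubled = ExpressionMatrix(
        doubled_values, value_scale=RAW_COUNTS,
        gene_gc=expr.gene_gc, gene_length=expr.gene_length,
    )
    out2 = cqn_normalize(doubled).values
    assert np.abs(out["s0"] - out2["s0"]).max() < 0.05


def test_cqn_permutation_equivariance():
    expr, _ = _biased_counts(seed=6, n_genes=400, gc_amplitude=1.0)
    out = cqn_normalize(expr)
    perm_genes = expr.values.index[::-1]
    perm_samples = list(expr.values.columns[::-1])
    shuffled = ExpressionMatrix(
        expr.values.loc[perm_genes, perm_samples].copy(), value_scale=RAW_COUNTS,
        gene_gc=expr.gene_gc.loc[perm_genes], gene_length=expr.gene_length.loc[perm_genes],
    )
    out_shuffled = cqn_normalize(shuffled)
    pd.testing.assert_frame_equal(
        out.values.loc[perm_genes, perm_samples], out_shuffled.values, atol=1e-10
    )


def test_cqn_preserves_sample_medians():
    expr, _ = _biased_counts(seed=7, gc_amplitude=1.5)
    pre_med = np.median(_log2_cpm(expr), axis=0)
    post_med = np.median(cqn_normalize(expr).values.to_numpy(), axis=0)
    np.testing.assert_allclose(pre_med, post_med, atol=1e-9)


def test_cqn_requires_annotation():
    expr = counts_matrix([[1, 2], [3, 4], [5, 6]], ["a", "b", "c"], ["x", "y"])
    with pytest.raises(ValueError, match="annotation"):
        cqn_normalize(expr)


def test_cqn_rejects_too_few_genes():
    expr, _ = _biased_counts(seed=8, n_genes=30)
    with pytest.raises(ValueError, match="too few genes"):
        cqn_normalize(expr, n_quantiles=5, spline_df=5)
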