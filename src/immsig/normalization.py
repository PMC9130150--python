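"""Log2-scale normalization of raw counts by two routes.

``normalize_housekeeping`` rescales each sample so its housekeeping-gene
geometric mean matches the grand geometric mean across samples — the
standard panel-count (NanoString-style) normalization with a designated
housekeeping set.

``cqn_normalize`` is a conditional-quantile normalizer for RNA-seq counts:
it removes library-size, GC-content and gene-length effects and returns
log2-scale expression.  The implementation fits additive spline quantile
regressions of log2 CPM on (GC, log10 length) at evenly spaced quantile
levels within each sample and interpolates each gene's systematic offset
between levels; the contract is the bias-removal property, not numerical
equality with any particular external tool.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import rankdata
from statsmodels.regression.quantile_regression import QuantReg

from .containers import ExpressionMatrix, LOG2_NORMALIZED, RAW_COUNTS


def normalize_housekeeping(
    expr: ExpressionMatrix,
    hk_genes: list[str],
    pseudocount: float = 0.5,
) -> ExpressionMatrix:
    """Housekeeping-anchored scaling followed by log2.

    Each sample's scale factor is (grand geometric mean of housekeeping
    counts over all samples) / (that sample's housekeeping geometric mean);
    all counts are multiplied by the factor, ``pseudocount`` is added and
    log2 taken.  Afterwards every sample has the same housekeeping geometric
    mean, and pure library-size differences are removed exactly.
    """
    if expr.value_scale != RAW_COUNTS:
        raise ValueError("housekeeping normalization expects raw counts")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    hk = sorted(set(hk_genes))  # set semantics: order and duplicates irrelevant
    if len(hk) < 2:
        raise ValueError("at least two housekeeping genes are required")
    missing = [g for g in hk if g not in expr.values.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")

    hk_counts = expr.values.loc[hk].to_numpy(dtype=float)
    zero_hk = (hk_counts <= 0).all(axis=0)
    if zero_hk.any():
        bad = [s for s, z in zip(expr.sample_ids, zero_hk) if z]
        raise ValueError(f"all-zero housekeeping counts in samples: {bad}")
    # geometric means on the positive housekeeping counts per sample
    with np.errstate(divide="ignore"):
        log_hk = np.where(hk_counts > 0, np.log(hk_counts), np.nan)
    sample_gm = np.exp(np.nanmean(log_hk, axis=0))
    grand_gm = np.exp(np.mean(np.log(sample_gm)))
    factors = grand_gm / sample_gm

    scaled = expr.values.to_numpy(dtype=float) * factors[None, :]
    values = pd.DataFrame(
        np.log2(scaled + pseudocount), index=expr.values.index, columns=expr.values.columns
    )
    return ExpressionMatrix(
        values,
        value_scale=LOG2_NORMALIZED,
        gene_gc=expr.gene_gc,
        gene_length=expr.gene_length,
    )


def _bspline_design(x: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with ~df basis columns over range(x)."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return np.ones((x.size, 1))
    n_interior = max(df - degree - 1, 0)
    if n_interior:
        interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
    else:
        interior = np.array([])
    pad = 1e-9 * max(1.0, abs(hi - lo))
    t = np.r_[[lo - pad] * (degree + 1), interior, [hi + pad] * (degree + 1)]
    return BSpline.design_matrix(x, t, degree).toarray()


def _quantile_fit(basis: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Fitted values of a linear quantile regression of y on the basis."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = QuantReg(y, basis).fit(q=tau, max_iter=2000)
    return basis @ np.asarray(res.params)


def cqn_normalize(
    expr: ExpressionMatrix,
    n_quantiles: int = 5,
    spline_df: int = 5,
) -> ExpressionMatrix:
    """Conditional-quantile normalization of counts to log2 scale.

    Steps: (1) y = log2 CPM with pseudocount 0.5; (2) within each sample, an
    additive spline quantile-regression surface of y on (GC, log10 length)
    is fitted at each of ``n_quantiles`` evenly spaced quantile levels;
    (3) each gene's systematic offset, interpolated between the level fits
    at the gene's own quantile, is subtracted; (4) the sample is re-centered
    to its pre-correction median.
    """
    if expr.value_scale != RAW_COUNTS:
        raise ValueError("cqn expects raw counts")
    if expr.gene_gc is None or expr.gene_length is None:
        raise ValueError("cqn requires per-gene GC and length annotation")
    if n_quantiles < 3 or spline_df < 3:
        raise ValueError("n_quantiles and spline_df must both be >= 3")

    counts = expr.values.to_numpy(dtype=float)
    g, n = counts.shape
    lib = expr.effective_library_size().to_numpy(dtype=float)
    y = np.log2((counts + 0.5) / lib[None, :] * 1e6)

    basis = np.column_stack(
        [
            np.ones(g),
            _bspline_design(expr.gene_gc.to_numpy(), spline_df)[:, 1:],
            _bspline_design(np.log10(expr.gene_length.to_numpy()), spline_df)[:, 1:],
        ]
    )
    p = basis.shape[1]
    if g < n_quantiles * (p + 1):
        raise ValueError(
            f"too few genes ({g}) for {n_quantiles} strata with {p} spline parameters"
        )

    levels = (np.arange(n_quantiles) + 0.5) / n_quantiles
    out = np.empty_like(y)
    for j in range(n):
        yj = y[:, j]
        med = np.median(yj)
        u = (rankdata(yj, method="average") - 0.5) / g
        # quantile-regression surface over all genes at each level
        offsets = np.zeros((n_quantiles, g))
        for k, tau in enumerate(levels):
            fit = _quantile_fit(basis, yj, tau)
            offsets[k] = fit - fit.mean()
        # interpolate each gene's offset across levels at its own quantile
        pos = np.clip(u * n_quantiles - 0.5, 0.0, n_quantiles - 1.0)
        k0 = np.floor(pos).astype(int)
        k1 = np.minimum(k0 + 1, n_quantiles - 1)
        lam = pos - k0
        cols = np.arange(g)
        off = (1.0 - lam) * offsets[k0, cols] + lam * offsets[k1, cols]
        corrected = yj - off
        out[:, j] = corrected + (med - np.median(corrected))

    values = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(
        values,
        value_scale=LOG2_NORMALIZED,
        gene_gc=expr.gene_gc,
        gene_length=expr.gene_length,
    )
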