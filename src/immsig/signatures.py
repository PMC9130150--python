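"""Composite immune-signature scoring and median dichotomization.

Two scoring rules are supported.  Subset panels use the log geometric mean:
the arithmetic mean of log2-normalized expression over the panel's genes
(equivalently, log2 of the geometric mean on the linear scale).  The
adaptive immune signature (AIS) averages normalized expression over its
genes and then standardizes across the cohort to mean 0 / variance 1
(n-1 denominator).  Continuous scores are dichotomized at the cohort median,
with "score <= median" assigned to the low group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import (
    AIS_STANDARDIZED_MEAN,
    ExpressionMatrix,
    GenePanel,
    LOG2_NORMALIZED,
    ScoreTable,
)

#: CD45 is scored as the single transcript PTPRC
CD45_GENE = "PTPRC"


def _require_log2(expr: ExpressionMatrix) -> None:
    if expr.value_scale != LOG2_NORMALIZED:
        raise ValueError("scoring requires log2-normalized expression")


def score_panel(
    expr: ExpressionMatrix,
    panel: GenePanel,
    missing_policy: str = "error",
) -> ScoreTable:
    """Log-geometric-mean composite score of a gene panel.

    The score is the mean of the panel genes' log2 values per sample; a
    single-gene panel (e.g. CD45 = PTPRC) reduces to that gene's log2 value.

    ``missing_policy``: ``"error"`` raises when any panel gene is absent;
    ``"drop_warn"`` warns and scores the present subset (erroring only when
    none remain).
    """
    _require_log2(expr)
    if missing_policy not in ("error", "drop_warn"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    present = [g for g in panel.genes if g in expr.values.index]
    missing = [g for g in panel.genes if g not in expr.values.index]
    if missing and missing_policy == "error":
        raise ValueError(f"panel {panel.name!r}: genes missing from matrix: {missing}")
    if not present:
        raise ValueError(f"panel {panel.name!r}: no panel genes present in matrix")
    if missing:
        warnings.warn(
            f"panel {panel.name!r}: dropping {len(missing)} missing genes: {missing}",
            stacklevel=2,
        )
    scores = expr.values.loc[present].mean(axis=0)
    return ScoreTable(panel_name=panel.name, scores=scores)


def score_ais(expr: ExpressionMatrix, ais_genes: list[str], panel_size: int = 17) -> ScoreTable:
    """Adaptive-immune-signature score: gene-averaged then cohort-standardized.

    ``raw_s`` is the mean of the normalized values of the signature genes for
    sample ``s``; the returned score is ``(raw_s - mean) / sd`` with the
    n-1-denominator standard deviation, so scores have mean 0 and sd 1.

    ``panel_size`` validates the gene-list length (17 for the AIS); pass the
    derived panel's own size when scoring a different signature.
    """
    _require_log2(expr)
    if len(set(ais_genes)) != len(ais_genes):
        raise ValueError("signature gene list contains duplicates")
    if len(ais_genes) != panel_size:
        raise ValueError(
            f"signature expects exactly {panel_size} genes, got {len(ais_genes)}"
        )
    if expr.n_samples < 2:
        raise ValueError("standardization requires at least two samples")
    missing = [g for g in ais_genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"signature genes missing from matrix: {missing}")
    raw = expr.values.loc[ais_genes].mean(axis=0)
    sd = raw.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("raw signature scores have zero variance; cannot standardize")
    scores = (raw - raw.mean()) / sd
    return ScoreTable(panel_name="AIS", scores=scores)


def score_any(expr: ExpressionMatrix, panel: GenePanel, missing_policy: str = "error") -> ScoreTable:
    """Dispatch on the panel's scoring method."""
    if panel.method == AIS_STANDARDIZED_MEAN:
        table = score_ais(expr, panel.genes, panel_size=len(panel.genes))
        return ScoreTable(panel_name=panel.name, scores=table.scores)
    return score_panel(expr, panel, missing_policy=missing_policy)


def dichotomize_median(scores: ScoreTable) -> ScoreTable:
    """Split at the cohort median: score <= median -> low, otherwise high.

    Ties at the median fall into the low group (the median sample is not
    called enriched), so group sizes differ by at most the number of samples
    tied at the cutoff.
    """
    if len(scores.scores) < 2:
        raise ValueError("median dichotomization requires at least two samples")
    cutoff = float(scores.scores.median())
    group = pd.Series(
        np.where(scores.scores > cutoff, "high", "low"), index=scores.scores.index
    )
    if (group == "high").sum() == 0:
        warnings.warn(
            f"panel {scores.panel_name!r}: all scores at or below the median; "
            "high group is empty",
            stacklevel=2,
        )
    return ScoreTable(
        panel_name=scores.panel_name, scores=scores.scores, group=group, cutoff=cutoff
    )
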