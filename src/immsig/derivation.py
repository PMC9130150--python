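"""Survival-supervised signature derivation.

The derivation recapitulates a three-stage procedure: (1) a univariate Cox
proportional-hazards screen of every gene against outcome, keeping genes
with p below a significance threshold; (2) a hypergeometric
over-representation test of the selected genes against annotated gene sets;
(3) assembly of a new signature panel from the genes shared between the
screen hits and the top-enriched set.  The whole pipeline is deterministic
given its inputs.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

from .containers import (
    AIS_STANDARDIZED_MEAN,
    ClinicalTable,
    EnrichmentResult,
    ExpressionMatrix,
    GenePanel,
    LOG2_NORMALIZED,
    ScreenResult,
)

logger = logging.getLogger(__name__)


def cox_screen(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    min_events: int = 10,
) -> tuple[list[ScreenResult], list[str]]:
    """Univariate Cox screen of each gene (standardized to unit SD).

    Fits one single-covariate Cox model per gene with Efron tie handling and
    returns per-gene Wald summaries plus the list of genes with p < alpha.
    Zero-variance genes are skipped with a logged reason.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if expr.value_scale != LOG2_NORMALIZED:
        raise ValueError("screen expects log2-normalized expression")
    common = [s for s in expr.sample_ids if s in clinical.data.index]
    if not common:
        raise ValueError("no shared samples between expression and clinical table")
    time = clinical.data.loc[common, "time"].to_numpy(dtype=float)
    event = clinical.data.loc[common, "event"].to_numpy(dtype=float)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in the clinical table; screen undefined")
    if n_events < min_events:
        raise ValueError(f"need >= {min_events} events for a stable screen, got {n_events}")
    mat = expr.values[common].to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite expression values")

    results: list[ScreenResult] = []
    skipped: list[str] = []
    for gene, row in zip(expr.gene_ids, mat):
        sd = row.std(ddof=1)
        if sd <= 0 or not np.isfinite(sd):
            logger.info("cox_screen: skipping %s (zero variance)", gene)
            skipped.append(gene)
            continue
        x = (row - row.mean()) / sd
        fit = PHReg(time, x[:, None], status=event, ties="efron").fit(disp=False)
        beta = float(fit.params[0])
        se = float(fit.bse[0])
        p = float(fit.pvalues[0])
        results.append(
            ScreenResult(gene_id=gene, log_hr=beta, se=se, p_value=p, n_events=n_events)
        )
    selected = [r.gene_id for r in results if r.p_value < alpha]
    return results, selected


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "log_hr": [r.log_hr for r in results],
            "se": [r.se for r in results],
            "p_value": [r.p_value for r in results],
            "n_events": [r.n_events for r in results],
        }
    )
    return frame.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def enrich_overrepresentation(
    selected: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of each gene set.

    Each set is intersected with the universe before testing; the p-value is
    P[X >= overlap] for X ~ Hypergeom(universe, set, selected).  Results are
    sorted ascending by p with Benjamini-Hochberg q-values attached.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    extra = set(selected) - universe_set
    if extra:
        raise ValueError(f"selected genes outside the universe: {sorted(extra)[:5]}")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    if not selected:
        warnings.warn("empty selection: all enrichment p-values are 1", stacklevel=2)
    sel = set(selected)
    M, N = len(universe_set), len(sel)

    results = []
    for name, genes in gene_sets.items():
        members = sorted(set(genes) & universe_set)
        overlap_genes = sorted(sel & set(members))
        k, n = len(overlap_genes), len(members)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, M, n, N))
        results.append(
            EnrichmentResult(
                set_name=name,
                universe_size=M,
                set_size=n,
                selected_size=N,
                overlap=k,
                p_value=min(p, 1.0),
                overlapping_genes=overlap_genes,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "universe_size": [r.universe_size for r in results],
            "set_size": [r.set_size for r in results],
            "selected_size": [r.selected_size for r in results],
            "overlap": [r.overlap for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "overlapping_genes": [",".join(r.overlapping_genes) for r in results],
        }
    )


def build_signature(
    top_set: EnrichmentResult,
    screen: list[ScreenResult],
    name: str,
) -> GenePanel:
    """Assemble a signature panel from the top enriched set's overlap genes.

    The panel is the intersection of screen-significant genes with the set
    (the set's ``overlapping_genes``), scored with the standardized-mean
    method.  Deterministic given its inputs.
    """
    if top_set.overlap < 1 or not top_set.overlapping_genes:
        raise ValueError(f"gene set {top_set.set_name!r} has empty overlap")
    screened = {r.gene_id for r in screen}
    stray = set(top_set.overlapping_genes) - screened
    if stray:
        raise ValueError(f"overlap genes absent from screen results: {sorted(stray)[:5]}")
    return GenePanel(
        name=name,
        genes=sorted(top_set.overlapping_genes),
        method=AIS_STANDARDIZED_MEAN,
    )
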