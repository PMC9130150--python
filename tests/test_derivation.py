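"""Tests for the Cox screen, over-representation test and panel assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immsig import (
    ExpressionMatrix,
    GenePanel,
    LOG2_NORMALIZED,
    build_signature,
    cox_screen,
    enrich_overrepresentation,
)
from immsig.containers import EnrichmentResult, ScreenResult

from conftest import make_survival_clinical
from oracles import cox_grid_mle, hypergeom_upper_tail


def _null_dataset(rng, n=300, n_genes=200):
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"P{i:03d}" for i in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(rng.normal(6, 1, (n_genes, n)), index=genes, columns=samples),
        value_scale=LOG2_NORMALIZED,
    )
    time = rng.exponential(5.0, n)
    censor = rng.uniform(0, 12, n)
    clinical = make_survival_clinical(np.minimum(time, censor), (time <= censor).astype(int))
    return expr, clinical


def test_null_screen_selects_at_alpha_rate(rng):
    """With no gene-outcome association the selected fraction sits within 3
    binomial standard errors of alpha."""
    expr, clinical = _null_dataset(rng)
    _, selected = cox_screen(expr, clinical, alpha=0.05)
    n_genes = expr.n_genes
    se = np.sqrt(n_genes * 0.05 * 0.95)
    assert abs(len(selected) - 0.05 * n_genes) < 3 * se


def test_screen_detects_real_effect():
    """A gene with per-SD log-HR -0.5 and ~200 events is selected in >= 90%
    of replicates."""
    hits = 0
    for rep in range(20):
        rng = np.random.default_rng(100 + rep)
        n = 500
        x = rng.normal(0, 1, n)
        time = rng.exponential(1.0 / (0.1 * np.exp(-0.5 * x)))
        censor = rng.uniform(0, 25, n)
        obs = np.minimum(time, censor)
        event = (time <= censor).astype(int)
        expr = ExpressionMatrix(
            pd.DataFrame(
                np.vstack([x, rng.normal(0, 1, n)]),
                index=["hit", "noise"],
                columns=[f"P{i:03d}" for i in range(n)],
            ),
            value_scale=LOG2_NORMALIZED,
        )
        clinical = make_survival_clinical(obs, event)
        assert event.sum() > 100
        _, selected = cox_screen(expr, clinical, alpha=0.05)
        hits += "hit" in selected
    assert hits >= 18


def test_constant_gene_skipped(rng):
    expr, clinical = _null_dataset(rng, n=80, n_genes=10)
    vals = expr.values.copy()
    vals.loc["g0"] = 4.0
    expr = ExpressionMatrix(vals, value_scale=LOG2_NORMALIZED)
    results, _ = cox_screen(expr, clinical)
    assert "g0" not in {r.gene_id for r in results}
    assert len(results) == 9


def test_screen_wald_consistency_and_oracle_match(rng):
    """Per-gene screen estimates agree with a grid-search maximizer of the
    hand-coded partial likelihood, and p-values match the Wald statistic."""
    n = 20
    x = rng.normal(0, 1, n)
    time = rng.exponential(1.0 / np.exp(0.4 * x))  # continuous: no ties
    clinical = make_survival_clinical(time, np.ones(n, int))
    expr = ExpressionMatrix(
        pd.DataFrame(x[None, :], index=["g"], columns=clinical.sample_ids),
        value_scale=LOG2_NORMALIZED,
    )
    results, _ = cox_screen(expr, clinical, min_events=10)
    r = results[0]
    x_std = (x - x.mean()) / x.std(ddof=1)
    beta_oracle = cox_grid_mle(time, np.ones(n, int), x_std)
    assert r.log_hr == pytest.approx(beta_oracle, abs=1e-3)
    assert r.p_value == pytest.approx(2 * stats.norm.sf(abs(r.log_hr / r.se)), rel=1e-6)


def test_screen_requires_events(rng):
    expr, clinical = _null_dataset(rng, n=40, n_genes=5)
    clinical.data["event"] = 0
    with pytest.raises(ValueError, match="no events"):
        cox_screen(expr, clinical)


# --- over-representation -----------------------------------------------------


def test_hypergeometric_worked_example():
    """Universe 20, set 5, selected 10, overlap 4: p = P[X >= 4] = 0.1517."""
    universe = [f"u{i}" for i in range(20)]
    gene_set = universe[:5]
    selected = universe[1:5] + universe[10:16]  # overlap u1..u4 = 4
    res = enrich_overrepresentation(selected, {"s": gene_set}, universe)
    assert res[0].overlap == 4
    assert res[0].p_value == pytest.approx(0.1517, abs=5e-5)
    assert res[0].p_value == pytest.approx(hypergeom_upper_tail(4, 20, 5, 10), rel=1e-12)


def test_disjoint_set_has_p_one():
    universe = [f"u{i}" for i in range(12)]
    res = enrich_overrepresentation(universe[:4], {"s": universe[8:]}, universe)
    assert res[0].overlap == 0
    assert res[0].p_value == 1.0


def test_saturated_selection_has_p_one():
    universe = [f"u{i}" for i in range(15)]
    sets = {"a": universe[:6], "b": universe[4:9]}
    res = enrich_overrepresentation(list(universe), sets, universe)
    for r in res:
        assert r.overlap == r.set_size
        assert r.p_value == pytest.approx(1.0)


def test_enrichment_matches_enumeration_on_small_universes(rng):
    """Agreement with brute-force hypergeometric enumeration for every
    random instance on universes of size <= 25."""
    for _ in range(25):
        m = int(rng.integers(5, 26))
        universe = [f"u{i}" for i in range(m)]
        set_size = int(rng.integers(1, m + 1))
        n_sel = int(rng.integers(1, m + 1))
        gene_set = list(rng.choice(universe, set_size, replace=False))
        selected = list(rng.choice(universe, n_sel, replace=False))
        res = enrich_overrepresentation(selected, {"s": gene_set}, universe)[0]
        expected = hypergeom_upper_tail(res.overlap, m, set_size, n_sel) if res.overlap else 1.0
        assert res.p_value == pytest.approx(min(expected, 1.0), rel=1e-10)


def test_empty_selection_warns_all_p_one():
    universe = [f"u{i}" for i in range(10)]
    with pytest.warns(UserWarning, match="empty selection"):
        res = enrich_overrepresentation([], {"s": universe[:3]}, universe)
    assert res[0].p_value == 1.0


def test_results_sorted_with_bh_qvalues(rng):
    universe = [f"u{i}" for i in range(30)]
    sets = {f"set{i}": list(rng.choice(universe, 8, replace=False)) for i in range(6)}
    selected = universe[:10]
    res = enrich_overrepresentation(selected, sets, universe)
    ps = [r.p_value for r in res]
    assert ps == sorted(ps)
    assert all(r.q_value is not None and r.q_value >= r.p_value - 1e-12 for r in res)


# --- signature assembly -------------------------------------------------------


def _screen_results(genes):
    return [ScreenResult(g, -0.3, 0.1, 0.01, 50) for g in genes]


def test_build_signature_uses_overlap_genes():
    overlap = [f"g{i}" for i in range(17)]
    top = EnrichmentResult("adaptive", 100, 20, 25, 17, 1e-8, overlap)
    panel = build_signature(top, _screen_results(overlap + ["extra"]), "ais")
    assert len(panel.genes) == 17
    assert panel.method == "ais_standardized_mean"
    assert set(panel.genes) == set(overlap)


def test_build_signature_single_gene_ok():
    top = EnrichmentResult("s", 50, 5, 3, 1, 0.2, ["lone"])
    panel = build_signature(top, _screen_results(["lone"]), "tiny")
    assert panel.genes == ["lone"]


def test_build_signature_rejects_empty_overlap():
    top = EnrichmentResult("s", 50, 5, 3, 0, 1.0, [])
    with pytest.raises(ValueError, match="empty overlap"):
        build_signature(top, _screen_results(["x"]), "nope")


def test_full_derivation_recovers_planted_signature(tmp_path):
    """End-to-end derive on a planted cohort recovers >= 80% of the true
    signature genes."""
    from immsig import PipelineConfig, SimConfig, generate_cohort, run_derive
    from immsig.io import write_gmt

    cfg = SimConfig(seed=17, n_samples=500, n_genes=200, infiltration_loading=1.2,
                    main_log_hr=-0.5, interaction_log_hr=0.0)
    cohort = generate_cohort(cfg)
    paths = cohort.write(tmp_path / "cohort")
    rng = np.random.default_rng(0)
    bg = [g for g in cohort.expression.gene_ids if g.startswith("BG")]
    sets = {
        "planted": cohort.truth["signature_genes"] + list(rng.choice(bg, 5, replace=False))
    }
    for i in range(4):
        sets[f"noise{i}"] = list(rng.choice(bg, 20, replace=False))
    write_gmt(sets, tmp_path / "sets.gmt")
    pc = PipelineConfig(
        expression=str(paths["expression"]), clinical=str(paths["clinical"]),
        gene_sets=str(tmp_path / "sets.gmt"),
        hk_genes=tuple(cohort.truth["housekeeping_genes"]),
        anti_her2_arms=("trastuzumab", "combination"),
        outdir=str(tmp_path / "out"),
    )
    panel, outputs = run_derive(pc)
    assert panel is not None
    truth = set(cohort.truth["signature_genes"])
    recovered = len(truth & set(panel.genes)) / len(truth)
    assert recovered >= 0.8
    assert (tmp_path / "out" / "screen.tsv").exists()
    assert (tmp_path / "out" / "enrichment.tsv").exists()
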