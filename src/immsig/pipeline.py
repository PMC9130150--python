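"""End-to-end pipeline orchestration: score, associate, derive, reproduce.

These functions are the library-level entry points behind the CLI.  Each one
reads delimited-text inputs, runs the corresponding analysis stage, writes
its outputs to the configured directory and returns the in-memory results.
All stages are deterministic given their inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .containers import ClinicalTable, ExpressionMatrix, GenePanel, ScoreTable, Table2x2
from .derivation import (
    build_signature,
    cox_screen,
    enrich_overrepresentation,
    enrichment_to_frame,
    screen_to_frame,
)
from .normalization import cqn_normalize, normalize_housekeeping
from .pcr import chi_square, logistic_pcr, odds_ratio, table_from_rates
from .signatures import dichotomize_median, score_any
from .survival import cox_fit, km_estimate, km_to_frame, logrank_test

logger = logging.getLogger(__name__)

DEFAULT_HK_GENES = ("B2M", "GAPDH", "POLR2A", "UBC", "YWHAZ")


def packaged_data(name: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(resources.files("immsig").joinpath("data", name))


@dataclass
class PipelineConfig:
    """File locations and analysis choices for the pipeline commands."""

    expression: str | None = None
    annotation: str | None = None
    clinical: str | None = None
    panels: str | None = None
    gene_sets: str | None = None
    scores: str | None = None
    normalizer: str = "housekeeping"  # or "cqn"
    hk_genes: tuple[str, ...] = DEFAULT_HK_GENES
    control_arms: tuple[str, ...] = ()
    anti_her2_arms: tuple[str, ...] = ()
    endpoint: str = "survival"  # or "pcr"
    screen_alpha: float = 0.05
    screen_arms: str = "anti_her2"  # or "all"
    seed: int = 0
    outdir: str = "immsig_out"

    def __post_init__(self) -> None:
        if self.normalizer not in ("housekeeping", "cqn"):
            raise ValueError(f"unknown normalizer {self.normalizer!r}")
        if self.endpoint not in ("survival", "pcr"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.screen_arms not in ("anti_her2", "all"):
            raise ValueError(f"screen_arms must be 'anti_her2' or 'all'")
        if not 0 < self.screen_alpha < 1:
            raise ValueError("screen_alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"pipeline config not found: {path}")
        spec = yaml.safe_load(path.read_text()) or {}
        for key in ("hk_genes", "control_arms", "anti_her2_arms"):
            if key in spec:
                spec[key] = tuple(spec[key])
        return cls(**spec)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_normalized(config: PipelineConfig) -> ExpressionMatrix:
    if not config.expression:
        raise ValueError("config must point at an expression file")
    expr = _io.read_expression(
        config.expression,
        annotation_path=config.annotation if config.normalizer == "cqn" else None,
    )
    if config.normalizer == "cqn":
        return cqn_normalize(expr)
    return normalize_housekeeping(expr, list(config.hk_genes))


def _arm_subsets(clinical: ClinicalTable, config: PipelineConfig) -> dict[str, list[str]]:
    arms = clinical.arms
    declared = set(config.control_arms) | set(config.anti_her2_arms)
    if declared and not set(arms) <= declared:
        raise ValueError(
            f"arm classification does not cover arms {sorted(set(arms) - declared)}"
        )
    subsets = {"all": list(clinical.data.index)}
    if config.control_arms:
        mask = clinical.data["arm"].isin(config.control_arms)
        subsets["control"] = list(clinical.data.index[mask])
    if config.anti_her2_arms:
        mask = clinical.data["arm"].isin(config.anti_her2_arms)
        subsets["anti_her2"] = list(clinical.data.index[mask])
    return subsets


def run_score(config: PipelineConfig) -> list[ScoreTable]:
    """Normalize, score every configured panel, dichotomize and write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = _load_normalized(config)
    panels = _io.read_panels(config.panels or packaged_data("default_panels.yaml"))
    tables = [dichotomize_median(score_any(expr, panel)) for panel in panels]
    _io.write_scores(tables, outdir / "scores.tsv")
    matrix = pd.DataFrame({t.panel_name: t.scores for t in tables})
    matrix.index.name = "sample_id"
    matrix.to_csv(outdir / "score_matrix.tsv", sep="\t")
    logger.info("run_score: %d panels, %d samples [config %s]",
                len(tables), expr.n_samples, config.config_hash())
    return tables


def run_associate(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Forest-table HRs, KM exports and per-arm pCR odds ratios for every panel."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.scores:
        raise ValueError("config must point at a scores file (run 'score' first)")
    tables = _io.read_scores(config.scores)
    clinical = _io.read_clinical(config.clinical) if config.clinical else None
    if clinical is None:
        raise ValueError("config must point at a clinical file")
    subsets = _arm_subsets(clinical, config)
    has_surv = {"time", "event"}.issubset(clinical.data.columns)
    adjust_ok = {"age", "nodal_status", "er_pr", "tumor_size", "grade"}.issubset(
        clinical.data.columns
    )

    forest_rows, km_frames, pcr_frames = [], [], []
    for table in tables:
        if table.group is None:
            table = dichotomize_median(table)
        high = (table.group == "high").astype(float)
        for subset, ids in subsets.items():
            sub = clinical.subset(ids)
            if has_surv:
                for adjusted in ([False, True] if adjust_ok else [False]):
                    fit = cox_fit(
                        sub,
                        high.loc[ids],
                        adjust="paper-default" if adjusted else None,
                        covariate_name=table.panel_name,
                    )
                    forest_rows.append(
                        {"panel": table.panel_name, "subset": subset,
                         "adjusted": adjusted, "hr": fit.hr, "ci_low": fit.ci_low,
                         "ci_high": fit.ci_high, "p_value": fit.p_value,
                         "n": fit.n, "n_events": fit.n_events}
                    )
                for grp in ("low", "high"):
                    ids_g = [s for s in ids if table.group.loc[s] == grp]
                    if not ids_g:
                        continue
                    curve = km_estimate(
                        sub.data.loc[ids_g, "time"], sub.data.loc[ids_g, "event"]
                    )
                    frame = km_to_frame(curve)
                    frame.insert(0, "group", grp)
                    frame.insert(0, "subset", subset)
                    frame.insert(0, "panel", table.panel_name)
                    km_frames.append(frame)
        if "pcr" in clinical.data.columns and clinical.data["pcr"].notna().all():
            ors = logistic_pcr(clinical, table, stratify_by_arm=True)
            ors.insert(0, "panel", table.panel_name)
            pcr_frames.append(ors)

    out: dict[str, pd.DataFrame] = {}
    if forest_rows:
        out["forest"] = pd.DataFrame(forest_rows)
        out["forest"].to_csv(outdir / "forest.tsv", sep="\t", index=False)
    if km_frames:
        out["km"] = pd.concat(km_frames, ignore_index=True)
        out["km"].to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    if pcr_frames:
        out["pcr"] = pd.concat(pcr_frames, ignore_index=True)
        out["pcr"].to_csv(outdir / "pcr_odds_ratios.tsv", sep="\t", index=False)
    logger.info("run_associate: wrote %s [config %s]", sorted(out), config.config_hash())
    return out


def run_derive(config: PipelineConfig) -> tuple[GenePanel | None, dict[str, pd.DataFrame]]:
    """Screen genes against outcome, test set over-representation, build a panel."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.gene_sets:
        raise ValueError("config must point at a GMT gene-set file")
    expr = _load_normalized(config)
    clinical = _io.read_clinical(config.clinical) if config.clinical else None
    if clinical is None:
        raise ValueError("config must point at a clinical file")
    gene_sets = _io.read_gmt(config.gene_sets)

    if config.screen_arms == "anti_her2" and config.anti_her2_arms:
        keep = clinical.data.index[clinical.data["arm"].isin(config.anti_her2_arms)]
        clinical = clinical.subset(list(keep))
        expr = ExpressionMatrix(
            expr.values[list(keep)], value_scale=expr.value_scale,
            gene_gc=expr.gene_gc, gene_length=expr.gene_length,
        )

    screen, selected = cox_screen(expr, clinical, alpha=config.screen_alpha)
    screen_frame = screen_to_frame(screen)
    screen_frame.to_csv(outdir / "screen.tsv", sep="\t", index=False)
    universe = [r.gene_id for r in screen]

    outputs = {"screen": screen_frame}
    if not selected:
        logger.warning("run_derive: no genes pass alpha=%s; empty panel", config.screen_alpha)
        (outdir / "derived_panel.yaml").write_text(
            "# no genes passed the screen; panel is empty\n{}\n"
        )
        return None, outputs
    enrichment = enrich_overrepresentation(selected, gene_sets, universe)
    enrich_frame = enrichment_to_frame(enrichment)
    enrich_frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    outputs["enrichment"] = enrich_frame
    top = enrichment[0]
    if top.overlap == 0:
        logger.warning("run_derive: top set has empty overlap; empty panel")
        (outdir / "derived_panel.yaml").write_text(
            "# top enriched set shares no genes with the screen hits\n{}\n"
        )
        return None, outputs
    panel = build_signature(top, screen, name=f"derived_{top.set_name}")
    _io.write_panels([panel], outdir / "derived_panel.yaml")
    logger.info("run_derive: %d-gene panel from set %r [config %s]",
                len(panel.genes), top.set_name, config.config_hash())
    return panel, outputs


def reproduce_printed_tables(outdir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Recompute the published contingency analyses from the shipped fixtures.

    Reconstructs each treatment arm's 2x2 pCR table from the printed
    rate-count pairs, computes high-vs-low odds ratios plus the
    combination-vs-trastuzumab OR among signature-low patients, and the
    Pearson chi-square on the printed ER/PR-by-signature-group table.
    """
    printed = pd.read_csv(packaged_data("table3_pcr.tsv"), sep="\t")
    arm_tables: dict[str, Table2x2] = {}
    rows = []
    for _, row in printed.iterrows():
        tab = table_from_rates(
            exposed=(int(row["pcr_high_count"]), float(row["pcr_high_pct"])),
            unexposed=(int(row["pcr_low_count"]), float(row["pcr_low_pct"])),
        )
        arm_tables[row["arm"]] = tab
        or_, ci, p = odds_ratio(tab, ci_method="wald")
        _, ci_prof, _ = odds_ratio(tab, ci_method="profile")
        rows.append(
            {"comparison": f"{row['arm']}: high vs low", "a": tab.a, "b": tab.b,
             "c": tab.c, "d": tab.d, "n": tab.total, "odds_ratio": round(or_, 2),
             "wald_ci_low": ci[0], "wald_ci_high": ci[1],
             "profile_ci_low": ci_prof[0], "profile_ci_high": ci_prof[1],
             "p_value": p}
        )
    # among signature-low patients: combination arm vs trastuzumab arm
    combo, tras = arm_tables["combination"], arm_tables["trastuzumab"]
    low_tab = Table2x2(a=combo.c, b=combo.d, c=tras.c, d=tras.d)
    or_, ci, p = odds_ratio(low_tab, ci_method="wald")
    _, ci_prof, _ = odds_ratio(low_tab, ci_method="profile")
    rows.append(
        {"comparison": "AIS-low: combination vs trastuzumab", "a": low_tab.a,
         "b": low_tab.b, "c": low_tab.c, "d": low_tab.d, "n": low_tab.total,
         "odds_ratio": round(or_, 2), "wald_ci_low": ci[0], "wald_ci_high": ci[1],
         "profile_ci_low": ci_prof[0], "profile_ci_high": ci_prof[1], "p_value": p}
    )
    or_frame = pd.DataFrame(rows)

    chars = pd.read_csv(packaged_data("table2_characteristics.tsv"), sep="\t")
    erpr = chars[chars["variable"] == "er_pr"]
    tab2 = Table2x2(
        a=int(erpr.loc[erpr["level"] == "negative", "ais_low"].iloc[0]),
        b=int(erpr.loc[erpr["level"] == "positive", "ais_low"].iloc[0]),
        c=int(erpr.loc[erpr["level"] == "negative", "ais_high"].iloc[0]),
        d=int(erpr.loc[erpr["level"] == "positive", "ais_high"].iloc[0]),
    )
    stat, dof, p = chi_square(tab2, correction=False)
    chi_frame = pd.DataFrame(
        [{"variable": "er_pr x signature group", "chi_square": stat, "df": dof,
          "p_value": round(p, 4)}]
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        or_frame.to_csv(outdir / "pcr_odds_ratios_printed.tsv", sep="\t", index=False)
        chi_frame.to_csv(outdir / "characteristics_chi_square.tsv", sep="\t", index=False)
    return {"odds_ratios": or_frame, "chi_square": chi_frame}
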