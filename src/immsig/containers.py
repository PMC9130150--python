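"""Core data containers shared across the pipeline.

Expression lives in a genes x samples :class:`pandas.DataFrame`; clinical
covariates in a sample-indexed frame.  Containers validate their invariants
at construction so downstream code can assume consistency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
LOG2_NORMALIZED = "log2_normalized"

#: ordinal encoding used when nodal status enters a regression
NODAL_LEVELS = ("N0", "N1", "N2", "N3")

#: the covariates used for adjusted hazard-ratio models
DEFAULT_ADJUSTMENT = ("age", "nodal_status", "er_pr", "tumor_size", "grade")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with optional gene annotation.

    Parameters
    ----------
    values
        Genes in rows (unique index), samples in columns (unique index).
    value_scale
        ``"raw_counts"`` (non-negative counts) or ``"log2_normalized"``.
    gene_gc
        Per-gene GC fraction in [0, 1], indexed like ``values``.
    gene_length
        Per-gene length in bp (positive), indexed like ``values``.
    library_size
        Per-sample sequencing depth / lane total.  When absent, the column
        sum is used wherever a library size is needed.
    """

    values: pd.DataFrame
    value_scale: str = RAW_COUNTS
    gene_gc: pd.Series | None = None
    gene_length: pd.Series | None = None
    library_size: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.value_scale not in (RAW_COUNTS, LOG2_NORMALIZED):
            raise ValueError(f"unknown value_scale {self.value_scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.value_scale == RAW_COUNTS and (arr < 0).any():
            raise ValueError("raw counts must be non-negative")
        for name in ("gene_gc", "gene_length"):
            ann = getattr(self, name)
            if ann is not None:
                ann = ann.reindex(self.values.index)
                if ann.isna().any():
                    missing = ann.index[ann.isna()].tolist()[:5]
                    raise ValueError(f"{name} missing for genes {missing}")
                setattr(self, name, ann.astype(float))
        if self.gene_gc is not None:
            if ((self.gene_gc < 0) | (self.gene_gc > 1)).any():
                raise ValueError("gene_gc must lie in [0, 1]")
        if self.gene_length is not None and (self.gene_length <= 0).any():
            raise ValueError("gene_length must be positive")
        if self.library_size is not None:
            ls = self.library_size.reindex(self.values.columns)
            if ls.isna().any() or (ls <= 0).any():
                raise ValueError("library_size must be positive for every sample")
            self.library_size = ls.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def effective_library_size(self) -> pd.Series:
        """Library size: supplied per-sample totals or the column sums."""
        if self.library_size is not None:
            return self.library_size
        return self.values.sum(axis=0).astype(float)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates, outcomes and treatment arm.

    ``data`` is indexed by sample id and must contain ``arm`` plus, for
    survival analyses, ``time`` (years, >= 0) and ``event`` (0/1).  Optional
    columns: ``pcr`` (0/1), ``age`` (years), ``tumor_size`` (cm),
    ``nodal_status`` (N0..N3 labels or 0..3 integers), ``grade`` (1..3),
    ``er_pr`` (1 = hormone-receptor positive).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if "arm" not in self.data.columns:
            raise ValueError("clinical table requires an 'arm' column")
        if "time" in self.data.columns:
            if (self.data["time"] < 0).any():
                raise ValueError("follow-up times must be >= 0")
        if "event" in self.data.columns:
            ev = set(pd.unique(self.data["event"].dropna()))
            if not ev <= {0, 1, 0.0, 1.0, True, False}:
                raise ValueError("event must be binary 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def arms(self) -> list[str]:
        return sorted(pd.unique(self.data["arm"]))

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())

    def covariate_frame(self, covariates: list[str]) -> pd.DataFrame:
        """Numeric design columns for the requested adjustment covariates.

        Nodal status and grade enter as ordinal integers; ER/PR as 0/1.
        """
        out = {}
        for cov in covariates:
            if cov not in self.data.columns:
                raise ValueError(f"clinical table lacks covariate {cov!r}")
            col = self.data[cov]
            if cov == "nodal_status" and col.dtype == object:
                codes = {lvl: i for i, lvl in enumerate(NODAL_LEVELS)}
                unknown = set(col.dropna()) - set(codes)
                if unknown:
                    raise ValueError(f"unknown nodal status labels {sorted(unknown)}")
                col = col.map(codes)
            out[cov] = pd.to_numeric(col)
        frame = pd.DataFrame(out, index=self.data.index)
        if frame.isna().any().any():
            raise ValueError("adjustment covariates contain missing values")
        return frame


LOG_GEOMETRIC_MEAN = "log_geometric_mean"
AIS_STANDARDIZED_MEAN = "ais_standardized_mean"


@dataclass
class GenePanel:
    """A named gene list and the composite-scoring method attached to it."""

    name: str
    genes: list[str]
    method: str = LOG_GEOMETRIC_MEAN

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.name!r} contains duplicate genes")
        if self.method not in (LOG_GEOMETRIC_MEAN, AIS_STANDARDIZED_MEAN):
            raise ValueError(f"unknown scoring method {self.method!r}")


@dataclass
class ScoreTable:
    """Continuous per-sample signature scores, optionally dichotomized."""

    panel_name: str
    scores: pd.Series  # indexed by sample id
    group: pd.Series | None = None  # 'high'/'low'
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate sample ids in score table")
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError("scores must be finite")
        if self.group is not None:
            if not self.group.index.equals(self.scores.index):
                raise ValueError("group index must match score index")
            bad = set(pd.unique(self.group)) - {"high", "low"}
            if bad:
                raise ValueError(f"invalid group labels {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"panel": self.panel_name, "score": self.scores})
        if self.group is not None:
            frame["group"] = self.group
            frame["cutoff"] = self.cutoff
        frame.index.name = "sample_id"
        return frame


@dataclass
class Table2x2:
    """2x2 contingency table: rows = exposure, columns = outcome yes/no."""

    a: int  # exposed, outcome
    b: int  # exposed, no outcome
    c: int  # unexposed, outcome
    d: int  # unexposed, no outcome

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table total must be positive")
        self.a, self.b, self.c, self.d = (int(x) for x in cells)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swap_rows(self) -> "Table2x2":
        return Table2x2(self.c, self.d, self.a, self.b)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SurvFit:
    """A fitted proportional-hazards term: HR, Wald CI and p-value."""

    term: str
    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    adjusted: bool
    covariates: tuple[str, ...] = ()
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence interval must bracket the HR")


@dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood variance and 95% CI."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time ``t`` (S=1 before first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class ScreenResult:
    """Per-gene univariate Cox screen summary (per-SD log hazard ratio)."""

    gene_id: str
    log_hr: float
    se: float
    p_value: float
    n_events: int


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of one gene set."""

    set_name: str
    universe_size: int
    set_size: int
    selected_size: int
    overlap: int
    p_value: float
    overlapping_genes: list[str]
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.selected_size):
            raise ValueError("overlap exceeds set or selection size")
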