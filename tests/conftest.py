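from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from immsig import (
    ClinicalTable,
    ExpressionMatrix,
    LOG2_NORMALIZED,
    SimConfig,
    generate_cohort,
    normalize_housekeeping,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_log2_matrix(values: dict[str, list[float]], samples: list[str]) -> ExpressionMatrix:
    """Small log2-scale matrix from {gene: per-sample values}."""
    frame = pd.DataFrame.from_dict(values, orient="index", columns=samples)
    return ExpressionMatrix(frame.astype(float), value_scale=LOG2_NORMALIZED)


def make_survival_clinical(times, events, arm="a", **extra) -> ClinicalTable:
    n = len(times)
    ids = [f"P{i:03d}" for i in range(n)]
    data = {"arm": [arm] * n, "time": list(times), "event": list(events)}
    data.update(extra)
    return ClinicalTable(pd.DataFrame(data, index=pd.Index(ids, name="sample_id")))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SimConfig(seed=11, n_samples=300, n_genes=200))


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    expr = normalize_housekeeping(
        default_cohort.expression, default_cohort.truth["housekeeping_genes"]
    )
    return default_cohort, expr


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
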