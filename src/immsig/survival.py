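"""Kaplan-Meier estimation, log-rank testing and Cox proportional-hazards fits.

The Kaplan-Meier estimator is computed directly (product-limit with
Greenwood variance and a log(-log) 95% CI).  The log-rank test delegates to
lifelines; Cox partial-likelihood maximization delegates to statsmodels
PHReg, which supports both Efron and Breslow tie handling.  Hazard ratios
are summarized with Wald confidence intervals on the log scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .containers import (
    ClinicalTable,
    DEFAULT_ADJUSTMENT,
    KMCurve,
    SurvFit,
)


def km_estimate(times, events, ci_method: str = "loglog", alpha: float = 0.05) -> KMCurve:
    """Product-limit survival estimate with Greenwood variance.

    ``ci_method`` is ``"loglog"`` (default; CI on the log(-log S) scale,
    guaranteed inside [0, 1]) or ``"plain"`` (symmetric Wald on S).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    if ci_method not in ("loglog", "plain"):
        raise ValueError(f"unknown ci_method {ci_method!r}")

    event_times = np.unique(times[events == 1])
    surv, var_sum = [], []
    n_at_risk = []
    s, gsum = 1.0, 0.0
    for t in event_times:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        n_at_risk.append(at_risk)
        s *= 1.0 - d / at_risk
        if at_risk > d:
            gsum += d / (at_risk * (at_risk - d))
        else:
            gsum = np.inf  # S hits zero; variance degenerate beyond here
        surv.append(s)
        var_sum.append(gsum)
    surv = np.array(surv)
    with np.errstate(invalid="ignore"):
        var = surv**2 * np.array(var_sum)
    var[surv == 0.0] = 0.0

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if ci_method == "plain":
            half = z * np.sqrt(var)
            lo, hi = np.clip(surv - half, 0, 1), np.clip(surv + half, 0, 1)
        else:
            # Greenwood on the log(-log S) scale
            se_cll = np.sqrt(np.array(var_sum)) / np.abs(np.log(surv))
            lo = surv ** np.exp(z * se_cll)
            hi = surv ** np.exp(-z * se_cll)
    interior = (surv > 0) & (surv < 1)
    lo = np.where(interior, lo, surv)
    hi = np.where(interior, hi, surv)
    return KMCurve(
        times=event_times,
        survival=surv,
        variance=var,
        ci_low=lo,
        ci_high=hi,
        n_at_risk=np.array(n_at_risk),
    )


def km_to_frame(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": curve.times,
            "survival": curve.survival,
            "greenwood_var": curve.variance,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
            "n_at_risk": curve.n_at_risk,
        }
    )


def logrank_test(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, int, float]:
    """Log-rank test across two or more groups of (times, events).

    Returns (chi-square statistic, degrees of freedom, p-value).
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {i} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    df = len(groups) - 1
    return float(res.test_statistic), df, float(res.p_value)


def cox_fit(
    clinical: ClinicalTable,
    covariate: pd.Series,
    adjust: list[str] | str | None = None,
    ties: str = "efron",
    covariate_name: str = "signature",
) -> SurvFit:
    """Cox PH fit of outcome on a per-sample covariate (score or 0/1 group).

    ``adjust`` may be None (univariate), the string ``"paper-default"``
    (age, nodal status, ER/PR, tumor size, grade) or an explicit covariate
    list.  Returns the Wald summary for the signature term.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    cov = covariate.reindex(clinical.data.index)
    if cov.isna().any():
        raise ValueError("covariate missing for some clinical samples")
    x = cov.to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("constant covariate carries no information")
    time = clinical.data["time"].to_numpy(dtype=float)
    event = clinical.data["event"].to_numpy(dtype=float)
    if event.sum() == 0:
        raise ValueError("no events; Cox model undefined")

    if adjust == "paper-default":
        adjust = list(DEFAULT_ADJUSTMENT)
    adjusted = bool(adjust)
    if adjusted:
        design = pd.concat(
            [pd.Series(x, index=clinical.data.index, name=covariate_name),
             clinical.covariate_frame(list(adjust))],
            axis=1,
        )
        sds = design.std(ddof=1)
        if (sds <= 0).any():
            dead = list(sds.index[sds <= 0])
            raise ValueError(f"constant adjustment covariates: {dead}")
        corr = np.corrcoef(design.to_numpy(), rowvar=False)
        offdiag = corr[np.triu_indices_from(corr, k=1)]
        if np.any(np.abs(offdiag) > 0.9999):
            raise ValueError("collinear covariates in adjusted model")
        exog = design.to_numpy(dtype=float)
        names = list(design.columns)
    else:
        exog = x[:, None]
        names = [covariate_name]

    model = PHReg(time, exog, status=event, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(disp=False)
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    converged = bool(np.isfinite(beta) and np.isfinite(se) and se > 0 and abs(beta) < 50)
    if not converged:
        warnings.warn(
            "Cox fit did not converge (possible separation / monotone likelihood)",
            stacklevel=2,
        )
        return SurvFit(
            term=covariate_name, log_hr=beta, se=se, hr=float(np.exp(beta)),
            ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
            n=len(time), n_events=int(event.sum()),
            adjusted=adjusted, covariates=tuple(names[1:]), converged=False,
        )
    z = stats.norm.ppf(0.975)
    return SurvFit(
        term=covariate_name,
        log_hr=beta,
        se=se,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(2.0 * stats.norm.sf(abs(beta / se))),
        n=len(time),
        n_events=int(event.sum()),
        adjusted=adjusted,
        covariates=tuple(names[1:]),
    )
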