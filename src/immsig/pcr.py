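"""Pathologic-complete-response contingency analyses.

Includes reconstruction of arm-level 2x2 tables from printed
"rate% (responders)" pairs, cross-product odds ratios with Wald or
profile-likelihood confidence intervals, Pearson chi-square tests, and
per-arm univariable logistic fits of pCR on signature group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from .containers import ClinicalTable, ScoreTable, Table2x2


def reconstruct_n(responders: int, percent: float, tolerance: float = 0.05) -> int:
    """Recover a denominator from a printed rate-count pair.

    ``n`` is the nearest integer to responders / (percent/100); the
    reconstruction must round-trip: |100 * responders / n - percent| <
    ``tolerance`` percentage points, otherwise nearby candidates are listed.
    """
    if responders < 0 or int(responders) != responders:
        raise ValueError("responders must be a non-negative integer")
    if responders == 0:
        raise ValueError("cannot reconstruct n from zero responders (unidentifiable)")
    if not 0 < percent <= 100:
        raise ValueError("percent must lie in (0, 100]")
    n = round(responders / (percent / 100.0))
    if n < responders:
        raise ValueError(f"reconstructed n={n} smaller than responders={responders}")
    err = abs(100.0 * responders / n - percent)
    if err >= tolerance:
        candidates = {
            m: round(abs(100.0 * responders / m - percent), 4)
            for m in range(max(responders, n - 3), n + 4)
        }
        raise ValueError(
            f"{percent}% ({responders}) fails validation at n={n} "
            f"(error {err:.4f} >= {tolerance}); candidates: {candidates}"
        )
    return int(n)


def table_from_rates(
    exposed: tuple[int, float], unexposed: tuple[int, float]
) -> Table2x2:
    """Build a 2x2 table from two printed (responders, percent) pairs."""
    a_resp, a_pct = exposed
    c_resp, c_pct = unexposed
    n1 = reconstruct_n(a_resp, a_pct)
    n0 = reconstruct_n(c_resp, c_pct)
    return Table2x2(a=a_resp, b=n1 - a_resp, c=c_resp, d=n0 - c_resp)


def _profile_ci(t: Table2x2, alpha: float = 0.05) -> tuple[float, float]:
    """Profile-likelihood CI for the odds ratio of a 2x2 table.

    Profiles the log-odds-ratio of the single-binary-covariate logistic
    likelihood, maximizing over the intercept at each candidate value.
    """
    a, b, c, d = t.a, t.b, t.c, t.d

    def max_loglik(psi: float) -> float:
        # intercept-profiled binomial log-likelihood at log-OR psi
        def nll(mu: float) -> float:
            p1 = 1.0 / (1.0 + np.exp(-(mu + psi)))
            p0 = 1.0 / (1.0 + np.exp(-mu))
            eps = 1e-12
            return -(
                a * np.log(p1 + eps) + b * np.log(1 - p1 + eps)
                + c * np.log(p0 + eps) + d * np.log(1 - p0 + eps)
            )
        res = optimize.minimize_scalar(nll, bounds=(-30, 30), method="bounded")
        return -float(res.fun)

    if min(a, b, c, d) > 0:
        psi_hat = np.log((a * d) / (b * c))
    else:
        # boundary MLE: OR -> 0 when a or d is 0, -> inf when b or c is 0
        psi_hat = -30.0 if (a == 0 or d == 0) else 30.0
    ll_hat = max_loglik(psi_hat)
    crit = stats.chi2.ppf(1 - alpha, df=1) / 2.0

    def deficit(psi: float) -> float:
        return ll_hat - max_loglik(psi) - crit

    lo_bracket, hi_bracket = psi_hat - 1.0, psi_hat + 1.0
    while deficit(lo_bracket) < 0 and lo_bracket > psi_hat - 60:
        lo_bracket -= 1.0
    while deficit(hi_bracket) < 0 and hi_bracket < psi_hat + 60:
        hi_bracket += 1.0
    lo = optimize.brentq(deficit, lo_bracket, psi_hat) if deficit(lo_bracket) >= 0 else -np.inf
    hi = optimize.brentq(deficit, psi_hat, hi_bracket) if deficit(hi_bracket) >= 0 else np.inf
    return float(np.exp(lo)), float(np.exp(hi))


def odds_ratio(
    t: Table2x2, ci_method: str = "wald", alpha: float = 0.05
) -> tuple[float, tuple[float, float], float]:
    """Cross-product odds ratio with CI and two-sided Wald p-value.

    OR = (a*d)/(b*c).  ``ci_method``: ``"wald"`` uses
    exp(log OR +/- z * sqrt(1/a+1/b+1/c+1/d)) and requires all cells > 0;
    ``"profile"`` inverts the logistic likelihood-ratio test.
    """
    if ci_method not in ("wald", "profile"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    cells = (t.a, t.b, t.c, t.d)
    if min(cells) == 0:
        if ci_method == "wald":
            raise ValueError(
                "zero cell: Wald odds ratio undefined; use ci_method='profile' "
                "or add a continuity correction upstream"
            )
        if t.b * t.c == 0:
            raise ValueError("zero denominator cell: odds ratio unbounded")
    or_ = (t.a * t.d) / (t.b * t.c)
    log_or = np.log(or_) if or_ > 0 else -np.inf
    if min(cells) > 0:
        se = np.sqrt(sum(1.0 / x for x in cells))
        p = float(2.0 * stats.norm.sf(abs(log_or / se)))
    else:
        se, p = np.nan, np.nan
    if ci_method == "wald":
        z = stats.norm.ppf(1 - alpha / 2)
        ci = (float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se)))
    else:
        ci = _profile_ci(t, alpha=alpha)
    return float(or_), ci, p


def chi_square(t: Table2x2, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square for a 2x2 table (Yates correction optional, off by
    default)."""
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=correction)
    return float(stat), int(dof), float(p)


def logistic_pcr(
    clinical: ClinicalTable,
    scores: ScoreTable,
    stratify_by_arm: bool = True,
    ci_method: str = "wald",
) -> pd.DataFrame:
    """Univariable logistic fit of pCR on signature group, per treatment arm.

    With a single binary covariate the fitted OR equals the 2x2
    cross-product OR; both Wald and (optionally) profile CIs are reported.
    Strata with only one outcome level are flagged as separated.
    """
    if scores.group is None:
        raise ValueError("scores must be dichotomized before logistic_pcr")
    if "pcr" not in clinical.data.columns:
        raise ValueError("clinical table lacks a 'pcr' column")
    data = clinical.data.copy()
    pcr = data["pcr"]
    if pcr.isna().any():
        raise ValueError("pcr contains missing values")
    group = scores.group.reindex(data.index)
    if group.isna().any():
        raise ValueError("scores missing for some clinical samples")
    high = (group == "high").astype(int)

    strata = data.groupby("arm").groups.items() if stratify_by_arm else [("all", data.index)]
    rows = []
    for arm, idx in strata:
        y = pcr.loc[idx].to_numpy(dtype=int)
        xg = high.loc[idx].to_numpy()
        tab = Table2x2(
            a=int(((xg == 1) & (y == 1)).sum()),
            b=int(((xg == 1) & (y == 0)).sum()),
            c=int(((xg == 0) & (y == 1)).sum()),
            d=int(((xg == 0) & (y == 0)).sum()),
        )
        separated = min(tab.a + tab.b, tab.c + tab.d) == 0 or y.min() == y.max()
        zero_cell = min(tab.a, tab.b, tab.c, tab.d) == 0
        if separated or (zero_cell and ci_method == "wald"):
            warnings.warn(f"arm {arm!r}: separation or zero cell in pCR table", stacklevel=2)
            rows.append(
                {"arm": arm, "n": tab.total, "pcr_high": tab.a, "n_high": tab.a + tab.b,
                 "pcr_low": tab.c, "n_low": tab.c + tab.d, "odds_ratio": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan, "flag": "separation"}
            )
            continue
        # logistic fit (cross-checkable against the cross-product OR)
        exog = sm.add_constant(xg.astype(float))
        logit_fit = sm.Logit(y, exog).fit(disp=False)
        or_logit = float(np.exp(logit_fit.params[1]))
        or_, ci, p = odds_ratio(tab, ci_method=ci_method)
        rows.append(
            {"arm": arm, "n": tab.total, "pcr_high": tab.a, "n_high": tab.a + tab.b,
             "pcr_low": tab.c, "n_low": tab.c + tab.d, "odds_ratio": or_logit,
             "or_crossproduct": or_, "ci_low": ci[0], "ci_high": ci[1],
             "p_value": p, "flag": ""}
        )
    return pd.DataFrame(rows)
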