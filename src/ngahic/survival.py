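"""Downstream survival and association statistics.

Kaplan-Meier product-limit curves, two-group log-rank tests, Cox
proportional-hazards regression (Efron tie handling) and 2x2 association
tests (two-sided Fisher exact / 1-df chi-square) linking classifier calls to
immunohistochemistry status.  Estimation is delegated to lifelines/scipy;
this module fixes the interfaces, endpoint conventions and error handling
used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

ALPHA = 0.05

#: the compact multivariate covariate adjustment (T-stage, histology grade,
#: invasion depth) and the extended set that adds manual grading and tumor
#: diameter; both are supported, neither is canonical.
MULTIVARIATE_COMPACT = ("t_stage_high", "histology_poor", "invasion_in")
MULTIVARIATE_EXTENDED = MULTIVARIATE_COMPACT + ("manual_grade_high", "diameter_ge5cm")

UNIVARIATE_COVARIATES = (
    "age_ge60",
    "t_stage_high",
    "histology_poor",
    "chemotherapy",
    "invasion_in",
    "diameter_ge5cm",
    "manual_grade_high",
    "ngahic",
)


@dataclass
class SurvivalSummary:
    variable: str
    hazard_ratio: float
    ci95: tuple[float, float]
    p_value: float

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.hazard_ratio <= hi):
            raise ValueError("hazard ratio outside its confidence interval")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must be in (0, 1]")


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with right censoring.

    Returns a DataFrame with columns ``time`` and ``survival``; the step
    function starts at S(0) = 1 and is non-increasing.
    """
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    if len(times) < 1:
        raise ValueError("need at least one observation")
    if np.any(times < 0):
        raise ValueError("negative times are not allowed")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)})


def logrank_2group(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, p-value)."""
    for arr in (times_a, times_b):
        if len(arr) == 0:
            raise ValueError("both groups must be non-empty")
    if int(np.sum(events_a)) + int(np.sum(events_b)) == 0:
        raise ValueError("at least one event is required")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def logrank_by_group(df: pd.DataFrame, group_col: str, time_col: str = "time_months", event_col: str = "event"):
    groups = df[group_col].unique()
    if len(groups) < 2:
        raise ValueError("log-rank requires >= 2 groups")
    g = sorted(groups)
    a = df[df[group_col] == g[0]]
    b = df[df[group_col] == g[1]]
    return logrank_2group(a[time_col], a[event_col], b[time_col], b[event_col])


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time_months",
    event_col: str = "event",
) -> list[SurvivalSummary]:
    """Cox partial-likelihood fit (Efron ties) with Wald CIs and p-values.

    Raises with a diagnostic on non-convergence or monotone likelihood.
    """
    n_events = int(cohort[event_col].sum())
    if n_events < len(covariates):
        raise ValueError(f"events ({n_events}) fewer than covariates ({len(covariates)})")
    data = cohort[[time_col, event_col, *covariates]].astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    se = cph.summary["se(coef)"].to_numpy(float)
    if np.any(~np.isfinite(se)) or np.any(np.abs(cph.params_.to_numpy(float)) > 20):
        raise RuntimeError(
            "Cox model diverged (monotone partial likelihood): a covariate "
            "perfectly separates the risk sets"
        )
    out = []
    for var in covariates:
        hr = float(np.exp(cph.params_[var]))
        lo = float(np.exp(cph.confidence_intervals_.loc[var].iloc[0]))
        hi = float(np.exp(cph.confidence_intervals_.loc[var].iloc[1]))
        p = float(cph.summary.loc[var, "p"])
        out.append(SurvivalSummary(variable=var, hazard_ratio=hr, ci95=(lo, hi), p_value=max(p, 1e-300)))
    return out


def univariate_cox(cohort: pd.DataFrame, covariates=UNIVARIATE_COVARIATES, **kw) -> list[SurvivalSummary]:
    """One single-covariate Cox fit per variable (the univariate table).

    Covariates whose fit diverges (monotone likelihood) are skipped with a
    log entry rather than failing the whole table.
    """
    import logging

    out = []
    for c in covariates:
        if c not in cohort.columns:
            continue
        try:
            out.append(cox_fit(cohort, [c], **kw)[0])
        except RuntimeError as exc:
            logging.getLogger(__name__).warning("univariate Cox for %r diverged: %s", c, exc)
    return out


def association_test(calls, marker, method: str = "fisher") -> tuple[float, float, np.ndarray]:
    """2x2 association between binary classifier calls and marker status.

    Returns ``(odds_ratio, p_value, table)``.  Fisher's exact p is two-sided
    by the point-probability rule; the chi-square statistic is the classic
    uncorrected 1-df version.
    """
    calls = np.asarray(calls).astype(int)
    marker = np.asarray(marker).astype(int)
    table = np.array(
        [
            [int(((calls == 1) & (marker == 1)).sum()), int(((calls == 1) & (marker == 0)).sum())],
            [int(((calls == 0) & (marker == 1)).sum()), int(((calls == 0) & (marker == 0)).sum())],
        ]
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("association test requires non-empty margins")
    a, b, c, d = table.ravel()
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    if method == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    elif method == "chisq":
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(odds), float(p), table
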