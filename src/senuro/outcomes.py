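"""Cohort filtering, renal endpoint derivation and biomarker evaluation.

The outcome arm asks whether a urinary biomarker threshold predicts CKD
progression.  Progression is a composite endpoint: reaching end-stage kidney
disease (start of renal replacement therapy, or an eGFR < 15 mL/min
maintained for more than 90 days) or a > 40% fall from baseline eGFR
maintained for more than 90 days.  Death is a censoring event.

Model fitting is delegated to the standard stacks — lifelines for
Kaplan-Meier / log-rank / Cox proportional hazards (Efron tie handling) and
statsmodels for OLS with variance-inflation factors — while the endpoint
rule, ROC threshold selection and exact U-statistic AUC are implemented
here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.api import OLS, add_constant
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .core_io import InputError, logger


@dataclass
class EndpointSpec:
    """Composite CKD-progression endpoint parameters."""

    eskd_egfr_threshold: float = 15.0   # mL/min
    sustain_days: float = 90.0
    decline_frac: float = 0.40

    def __post_init__(self):
        if not 0 < self.decline_frac < 1:
            raise InputError("decline_frac must lie in (0, 1)")
        if self.sustain_days <= 0:
            raise InputError("sustain_days must be positive")


@dataclass
class SurvivalRecord:
    id: str
    time: float
    event: bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.time <= 0:
            raise InputError(f"record {self.id}: time must be positive")


def outcome_cohort_filter(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the outcome-cohort exclusion rules.

    Excludes, in order: rows with missing baseline eGFR or uACR
    ("missing_data"); low-progression-risk rows with eGFR >= 60 AND
    uACR <= 30 ("low_risk"); rows with eGFR < 20 ("low_egfr").  Returns the
    included rows and a per-rule exclusion tally.
    """
    for col in ("baseline_egfr", "uacr"):
        if col not in df.columns:
            raise InputError(f"cohort table is missing column '{col}'")
    missing = df["baseline_egfr"].isna() | df["uacr"].isna()
    rest = df[~missing]
    low_risk = (rest["baseline_egfr"] >= 60.0) & (rest["uacr"] <= 30.0)
    rest2 = rest[~low_risk]
    low_egfr = rest2["baseline_egfr"] < 20.0
    included = rest2[~low_egfr]
    tally = {
        "total": int(len(df)),
        "missing_data": int(missing.sum()),
        "low_risk": int(low_risk.sum()),
        "low_egfr": int(low_egfr.sum()),
        "included": int(len(included)),
    }
    return included.copy(), tally


def _first_sustained_below(
    series: Sequence[tuple[float, float]], threshold: float, sustain_days: float
) -> Optional[float]:
    """Day of the first below-threshold measurement that stays below.

    A measurement m qualifies when every later measurement up to and
    including the first one more than ``sustain_days`` after m is also below
    the threshold, and such a confirmatory measurement exists.
    """
    for i, (day_i, val_i) in enumerate(series):
        if val_i >= threshold:
            continue
        confirmed = False
        violated = False
        for day_j, val_j in series[i + 1:]:
            if val_j >= threshold:
                violated = True
                break
            if day_j > day_i + sustain_days:
                confirmed = True
                break
        if confirmed and not violated:
            return day_i
    return None


def derive_endpoint(
    series: Sequence[tuple[float, float]],
    baseline_egfr: float,
    rrt_start: Optional[float],
    death: Optional[float],
    last_followup: float,
    spec: EndpointSpec = EndpointSpec(),
    record_id: str = "",
) -> SurvivalRecord:
    """Composite progression endpoint from an eGFR visit series.

    The event time is the earliest of: RRT start; the first measurement
    sustained below 15 mL/min; the first measurement sustained below
    (1 - decline_frac) x baseline.  Without an event, follow-up is censored
    at the earlier of death and last follow-up.
    """
    if baseline_egfr <= 0:
        raise InputError("baseline eGFR must be positive")
    days = [d for d, _ in series]
    if days != sorted(days):
        raise InputError("eGFR series must be time-sorted")

    candidates = []
    if rrt_start is not None:
        candidates.append(rrt_start)
    for threshold in (
        spec.eskd_egfr_threshold,
        (1.0 - spec.decline_frac) * baseline_egfr,
    ):
        t = _first_sustained_below(series, threshold, spec.sustain_days)
        if t is not None:
            candidates.append(t)
    if candidates:
        t_event = min(candidates)
        return SurvivalRecord(id=record_id, time=max(t_event, 1e-9), event=True)
    t_censor = min(death, last_followup) if death is not None else last_followup
    return SurvivalRecord(id=record_id, time=max(t_censor, 1e-9), event=False)


def auc_u_statistic(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney U statistic over n1*n2 (midranks for ties)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise InputError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float) -> tuple:
    """DeLong variance-based 95% CI for a single AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement values via midranks
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    half = 1.96 * math.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def roc(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> dict:
    """Empirical ROC with exact U-statistic AUC and a 95% CI.

    A case is predicted positive when its score is >= the threshold.  The CI
    is a stratified bootstrap over ``n_boot`` seeded resamples by default;
    ``ci_method='delong'`` uses the DeLong asymptotic variance instead.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if len(set(y.tolist())) < 2:
        raise InputError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    auc = auc_u_statistic(s, y)
    if ci_method == "delong":
        ci = _delong_ci(s, y, auc)
    else:
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        boot = np.empty(n_boot)
        for k in range(n_boot):
            bi = np.concatenate(
                [
                    rng.choice(pos_idx, size=len(pos_idx), replace=True),
                    rng.choice(neg_idx, size=len(neg_idx), replace=True),
                ]
            )
            boot[k] = auc_u_statistic(s[bi], y[bi])
        ci = tuple(np.quantile(boot, [0.025, 0.975]))
    return {
        "thresholds": thresholds,
        "sens": tpr,
        "spec": 1.0 - fpr,
        "auc": auc,
        "ci": ci,
        "ci_method": ci_method,
    }


def select_threshold(roc_result: dict, min_specificity: float = 0.9) -> float:
    """Threshold maximising sensitivity subject to a specificity floor.

    Ties go to higher specificity, then to the lower threshold value.  If no
    threshold attains the floor, the maximum-specificity threshold is
    returned with a warning.
    """
    thr = np.asarray(roc_result["thresholds"], float)
    sens = np.asarray(roc_result["sens"], float)
    spec = np.asarray(roc_result["spec"], float)
    finite = np.isfinite(thr)
    thr, sens, spec = thr[finite], sens[finite], spec[finite]
    ok = spec >= min_specificity
    if not ok.any():
        logger.warning(
            "no threshold reaches specificity %.2f; returning the "
            "max-specificity threshold",
            min_specificity,
        )
        ok = spec == spec.max()
    order = sorted(
        np.flatnonzero(ok), key=lambda i: (-sens[i], -spec[i], thr[i])
    )
    return float(thr[order[0]])


def linreg_senescence(
    df: pd.DataFrame, y: str = "pct_senescent", xs: Sequence[str] = ()
) -> dict:
    """OLS of the senescent fraction on biomarker and clinical covariates.

    Returns coefficient estimates, two-sided t-test p-values and the
    variance inflation factor of each covariate.
    """
    xs = list(xs)
    if len(df) <= len(xs) + 1:
        raise InputError("need n > number of covariates + 1")
    X = add_constant(df[xs].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise InputError("singular design matrix")
    fit = OLS(df[y].astype(float), X).fit()
    vif = {
        name: float(variance_inflation_factor(X.to_numpy(), i))
        for i, name in enumerate(X.columns)
        if name != "const"
    }
    return {
        "estimates": fit.params.drop("const").to_dict(),
        "intercept": float(fit.params["const"]),
        "p": fit.pvalues.drop("const").to_dict(),
        "vif": vif,
        "r2": float(fit.rsquared),
    }


def km_logrank(
    df: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    group_col: str = "uccr_high",
) -> dict:
    """Kaplan-Meier curves per group with a two-group log-rank test."""
    groups = df[group_col].unique()
    if len(groups) != 2:
        raise InputError("exactly two groups are required")
    curves = {}
    subsets = {}
    for g in groups:
        sub = df[df[group_col] == g]
        if len(sub) == 0:
            raise InputError(f"group {g} is empty")
        km = KaplanMeierFitter()
        km.fit(sub[duration_col], sub[event_col], label=str(g))
        curves[g] = km.survival_function_
        subsets[g] = sub
    if df[event_col].sum() == 0:
        raise InputError("no events observed")
    g0, g1 = sorted(groups)
    res = logrank_test(
        subsets[g0][duration_col],
        subsets[g1][duration_col],
        event_observed_A=subsets[g0][event_col],
        event_observed_B=subsets[g1][event_col],
    )
    return {"curves": curves, "chi2": float(res.test_statistic),
            "p": float(res.p_value)}


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Cox proportional-hazards fit (Efron ties) with diagnostics.

    Returns per-covariate hazard ratios with Wald 95% CIs and p-values, the
    Harrell c-index of the fitted model, and a proportional-hazards test
    p-value per covariate (correlation of scaled Schoenfeld residuals with
    event rank time).
    """
    covariates = list(covariates)
    if df[event_col].sum() == 0:
        raise InputError("no events observed")
    for c in covariates:
        if df[c].nunique() < 2:
            raise InputError(f"covariate '{c}' is constant")
    data = df[[duration_col, event_col] + covariates]
    cph = CoxPHFitter()
    cph.fit(data, duration_col=duration_col, event_col=event_col)
    summary = cph.summary
    ph = proportional_hazard_test(cph, data, time_transform="rank")
    ph_p = ph.summary["p"]
    per_cov = {
        c: {
            "hr": float(summary.loc[c, "exp(coef)"]),
            "ci_low": float(summary.loc[c, "exp(coef) lower 95%"]),
            "ci_high": float(summary.loc[c, "exp(coef) upper 95%"]),
            "p": float(summary.loc[c, "p"]),
            "ph_test_p": float(ph_p.loc[c]),
        }
        for c in covariates
    }
    return {"covariates": per_cov, "c_index": float(cph.concordance_index_)}


def c_index_delta(
    df: pd.DataFrame,
    covariates_with: Sequence[str],
    covariates_without: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Harrell c-index of nested Cox models on the same records."""
    fit_with = cox_fit(df, covariates_with, duration_col, event_col)
    fit_without = cox_fit(df, covariates_without, duration_col, event_col)
    return {"c_with": fit_with["c_index"], "c_without": fit_without["c_index"]}
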