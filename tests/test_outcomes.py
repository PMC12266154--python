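"""Cohort filter, endpoint rule, ROC/threshold, regression and survival."""

import math

import numpy as np
import pandas as pd
import pytest

from senuro.core_io import InputError
from senuro.outcomes import (
    EndpointSpec,
    auc_u_statistic,
    c_index_delta,
    cox_fit,
    derive_endpoint,
    km_logrank,
    linreg_senescence,
    outcome_cohort_filter,
    roc,
    select_threshold,
)


class TestCohortFilter:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["baseline_egfr", "uacr"])

    def test_low_risk_requires_both_conjuncts(self):
        df = self._df([(70, 10), (70, 50), (50, 10)])
        included, tally = outcome_cohort_filter(df)
        assert tally["low_risk"] == 1
        assert len(included) == 2  # (70,50) and (50,10) stay

    def test_low_egfr_exclusion(self):
        df = self._df([(19, 100), (20, 100), (45, 100)])
        included, tally = outcome_cohort_filter(df)
        assert tally["low_egfr"] == 1 and len(included) == 2

    def test_missing_data_tally(self):
        df = self._df([(np.nan, 10), (50, np.nan), (50, 50)])
        _, tally = outcome_cohort_filter(df)
        assert tally["missing_data"] == 2 and tally["included"] == 1


class TestDeriveEndpoint:
    def test_sustained_forty_percent_decline(self):
        # baseline 50 -> threshold 30; drop at day 100 confirmed at day 400
        series = [(0, 50), (50, 45), (100, 25), (200, 27), (300, 26), (400, 28)]
        rec = derive_endpoint(series, 50, None, None, 1000)
        assert rec.event and rec.time == 100

    def test_transient_dip_is_not_an_event(self):
        series = [(0, 50), (100, 25), (150, 35), (400, 20)]
        rec = derive_endpoint(series, 50, None, None, 1000)
        assert not rec.event and rec.time == 1000

    def test_rrt_dominates(self):
        rec = derive_endpoint([(0, 50), (100, 45)], 50, 30.0, None, 1000)
        assert rec.event and rec.time == 30.0

    def test_death_censors_before_followup(self):
        rec = derive_endpoint([(0, 50), (100, 45)], 50, None, 500.0, 1000)
        assert not rec.event and rec.time == 500.0

    def test_eskd_threshold_when_decline_rule_is_weaker(self):
        # baseline 20: 40% rule threshold is 12, but eGFR < 15 sustained
        series = [(0, 20), (100, 14), (200, 13), (250, 14)]
        rec = derive_endpoint(series, 20, None, None, 1000)
        assert rec.event and rec.time == 100

    def test_confirmation_requires_measurement_beyond_window(self):
        # below threshold at day 100 but nothing measured after day 190
        series = [(0, 50), (100, 25), (150, 26)]
        rec = derive_endpoint(series, 50, None, None, 1000)
        assert not rec.event

    def test_redundant_measurements_do_not_change_event(self):
        series = [(0, 50), (100, 25), (200, 27), (400, 28)]
        rec1 = derive_endpoint(series, 50, None, None, 1000)
        padded = [(0, 50), (100, 25), (150, 24), (200, 27), (350, 29), (400, 28)]
        rec2 = derive_endpoint(padded, 50, None, None, 1000)
        assert rec1.event == rec2.event and rec1.time == rec2.time

    def test_unsorted_series_rejected(self):
        with pytest.raises(InputError):
            derive_endpoint([(10, 50), (0, 60)], 60, None, None, 100)


class TestRoc:
    def test_perfect_separation(self):
        res = roc([1, 2, 3, 4], [0, 0, 1, 1], n_boot=50, seed=0)
        assert res["auc"] == pytest.approx(1.0)
        t = select_threshold(res, min_specificity=0.9)
        sens = res["sens"][np.where(res["thresholds"] == t)][0]
        assert sens == pytest.approx(1.0)

    def test_hand_u_statistic(self):
        assert auc_u_statistic([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=8)
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 1])
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum(
            (1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg
        )
        assert auc_u_statistic(scores, labels) == pytest.approx(
            wins / (len(pos) * len(neg))
        )

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.4).astype(int)
        a = auc_u_statistic(scores, labels)
        b = auc_u_statistic(scores, 1 - labels)
        assert a == pytest.approx(1.0 - b)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc([1, 2, 3], [1, 1, 1])

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        res = roc(scores, labels, n_boot=200, seed=3)
        assert res["ci"][0] <= res["auc"] <= res["ci"][1]
        delong = roc(scores, labels, ci_method="delong")
        assert delong["ci"][0] <= delong["auc"] <= delong["ci"][1]


class TestSelectThreshold:
    def test_matches_exhaustive_search(self):
        scores = np.array([0.1, 0.3, 0.35, 0.4, 0.55, 0.6, 0.7, 0.8, 0.9, 0.95])
        labels = np.array([0, 0, 1, 0, 1, 0, 1, 1, 0, 1])
        res = roc(scores, labels, n_boot=10, seed=0)
        chosen = select_threshold(res, min_specificity=0.6)

        # brute force over every candidate threshold
        best = None
        for t in np.unique(scores):
            sens = ((scores >= t) & (labels == 1)).sum() / labels.sum()
            spec = ((scores < t) & (labels == 0)).sum() / (1 - labels).sum()
            if spec >= 0.6:
                key = (-sens, -spec, t)
                if best is None or key < best[0]:
                    best = (key, t)
        assert chosen == pytest.approx(best[1])

    def test_zero_floor_maximises_sensitivity(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        res = roc(scores, labels, n_boot=10, seed=0)
        t = select_threshold(res, min_specificity=0.0)
        # sensitivity is maximal at any threshold <= 2; the tie breaks
        # toward the higher-specificity choice, threshold 2
        assert ((scores >= t) & (labels == 1)).sum() == labels.sum()
        assert t == pytest.approx(2.0)


class TestLinreg:
    def test_orthogonal_predictors_unit_vif(self):
        n = 40
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": x1 + 0.5 * x2})
        out = linreg_senescence(df, y="y", xs=["x1", "x2"])
        assert out["vif"]["x1"] == pytest.approx(1.0)
        assert out["vif"]["x2"] == pytest.approx(1.0)

    def test_exact_fit_recovers_coefficient(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"x": x, "y": 2.0 * x})
        out = linreg_senescence(df, y="y", xs=["x"])
        assert out["estimates"]["x"] == pytest.approx(2.0)
        assert out["p"]["x"] < 1e-10

    def test_matches_normal_equations_oracle(self):
        df = pd.DataFrame(
            {
                "x1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "x2": [2.0, 1.0, 4.0, 3.0, 7.0, 5.0],
                "y": [1.1, 1.9, 3.2, 3.8, 6.1, 5.4],
            }
        )
        out = linreg_senescence(df, y="y", xs=["x1", "x2"])
        X = np.column_stack([np.ones(6), df.x1, df.x2])
        beta = np.linalg.solve(X.T @ X, X.T @ df.y.to_numpy())
        assert out["intercept"] == pytest.approx(beta[0])
        assert out["estimates"]["x1"] == pytest.approx(beta[1])
        assert out["estimates"]["x2"] == pytest.approx(beta[2])

    def test_singular_design_rejected(self):
        df = pd.DataFrame({"x1": [1.0, 2.0, 3.0, 4.0]})
        df["x2"] = 2 * df.x1
        df["y"] = df.x1
        with pytest.raises(InputError):
            linreg_senescence(df, y="y", xs=["x1", "x2"])


def _toy_survival():
    # two groups, distinct event times, no ties
    return pd.DataFrame(
        {
            "time": [5.0, 8.0, 12.0, 20.0, 3.0, 9.0, 15.0, 25.0],
            "event": [1, 1, 0, 1, 1, 1, 1, 0],
            "uccr_high": [1, 1, 1, 1, 0, 0, 0, 0],
        }
    )


def logrank_score_oracle(df):
    """Log-rank chi2 as the Cox score test at beta = 0 (hand risk sets)."""
    u = v = 0.0
    for _, row in df[df.event == 1].iterrows():
        at_risk = df[df.time >= row.time]
        n = len(at_risk)
        n1 = at_risk.uccr_high.sum()
        u += row.uccr_high - n1 / n
        if n > 1:
            v += (n1 / n) * (1 - n1 / n)
    return u * u / v


class TestSurvival:
    def test_identical_groups_null_chi2(self):
        df = pd.DataFrame(
            {
                "time": [5.0, 8.0, 12.0, 5.5, 8.5, 12.5],
                "event": [1, 1, 0, 1, 1, 0],
                "uccr_high": [1, 1, 1, 0, 0, 0],
            }
        )
        res = km_logrank(df)
        assert res["chi2"] < 0.2

    def test_logrank_matches_score_test_oracle(self):
        df = _toy_survival()
        res = km_logrank(df)
        assert res["chi2"] == pytest.approx(logrank_score_oracle(df), abs=1e-6)

    def test_survival_zero_after_all_events(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 1.5, 2.5, 3.5],
             "event": [1, 1, 1, 1, 1, 1],
             "uccr_high": [0, 0, 0, 1, 1, 1]}
        )
        res = km_logrank(df)
        for curve in res["curves"].values():
            assert curve.iloc[-1, 0] == pytest.approx(0.0)

    @pytest.mark.filterwarnings("ignore::lifelines.exceptions.ConvergenceWarning")
    def test_cox_perfectly_concordant_risk_score(self):
        # complete separation: the coefficient diverges but concordance is
        # well-defined and must be exactly 1
        df = pd.DataFrame(
            {
                "time": [10.0, 8.0, 6.0, 4.0, 2.0, 12.0],
                "event": [1, 1, 1, 1, 1, 0],
                "risk": [1.0, 2.0, 3.0, 4.0, 5.0, 0.5],
            }
        )
        out = cox_fit(df, ["risk"])
        assert out["c_index"] == pytest.approx(1.0)

    def test_constant_covariate_rejected(self):
        df = _toy_survival().assign(flat=1.0)
        with pytest.raises(InputError):
            cox_fit(df, ["flat"])

    def test_no_events_rejected(self):
        df = _toy_survival().assign(event=0)
        with pytest.raises(InputError):
            cox_fit(df, ["uccr_high"])

    def test_duplicate_covariate_sets_identical_c(self):
        rng = np.random.default_rng(4)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.5 * x))
        df = pd.DataFrame({"time": t, "event": 1, "x": x})
        out = c_index_delta(df, ["x"], ["x"])
        assert out["c_with"] == out["c_without"]

    def test_pure_noise_covariate_leaves_c_index(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.7 * x))
        c = rng.exponential(2.0, size=n)
        df = pd.DataFrame(
            {"time": np.minimum(t, c), "event": (t <= c).astype(int),
             "x": x, "noise": noise}
        )
        out = c_index_delta(df, ["x", "noise"], ["x"])
        assert abs(out["c_with"] - out["c_without"]) < 0.01
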