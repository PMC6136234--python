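"""Cohort statistics: group comparisons, correlations, regressions, pairing."""

import numpy as np
import pandas as pd
import pytest

from _oracles import holm_by_hand
from glucodyn.errors import ParameterError
from glucodyn.stats import (
    CORE_MODEL_TERMS,
    compare_groups,
    holm_adjust,
    paired_before_after,
    spearman_matrix,
    standardized_regression,
    stepwise_forward,
    tir_models,
)


def null_table(rng, n_per_group=10):
    rows = []
    for g in ("A", "B", "C"):
        for i in range(n_per_group):
            rows.append({"group": g, "metric": rng.standard_normal()})
    return pd.DataFrame(rows)


def synthetic_cohort(rng, n=120):
    """Covariates plus indices with known construction for recovery tests."""
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": rng.choice(["T1D", "T2D"], size=n),
            "age": rng.normal(55, 10, n),
            "sex": rng.choice(["M", "F"], size=n),
            "diabetes_duration": rng.uniform(1, 25, n),
            "bmi": rng.normal(28, 4, n),
            "carb_intake": rng.normal(180, 40, n),
            "therapy_code": rng.integers(2, 5, n),
        }
    )
    df["sd1"] = rng.uniform(0.5, 2.0, n)
    df["sd2"] = df["sd1"] * rng.uniform(1.5, 3.0, n)
    df["afe"] = np.pi * df["sd1"] * df["sd2"]
    df["cv_percent"] = 10 * df["sd2"] + rng.normal(0, 2, n)
    df["tir_hours_per_day"] = np.clip(24 - 4 * df["sd2"] + rng.normal(0, 0.5, n), 0, 24)
    return df


class TestHolm:
    def test_hand_worked_example(self):
        adj = holm_adjust(np.array([0.01, 0.04, 0.03]))
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])

    def test_agrees_with_hand_rule(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(2, 8)))
            np.testing.assert_allclose(holm_adjust(p), holm_by_hand(p), atol=1e-12)

    def test_never_below_raw(self, rng):
        p = rng.uniform(0, 1, size=6)
        assert np.all(holm_adjust(p) >= p - 1e-15)


class TestCompareGroups:
    def test_shifted_group_detected_identical_pair_not(self, rng):
        df = null_table(rng)
        df.loc[df.group == "C", "metric"] += 10 * df["metric"].std()
        res = compare_groups(df, "metric")
        pw = res.pairwise.set_index(["group_a", "group_b"])
        assert pw.loc[("A", "C"), "p_holm"] < 0.001
        assert pw.loc[("B", "C"), "p_holm"] < 0.001
        assert pw.loc[("A", "B"), "p_holm"] > 0.05

    def test_needs_two_groups_of_two(self):
        df = pd.DataFrame({"group": ["A", "A", "B"], "metric": [1.0, 2.0, 3.0]})
        with pytest.raises(ParameterError):
            compare_groups(df, "metric")

    def test_anova_and_pairwise_shapes(self, rng):
        res = compare_groups(null_table(rng), "metric")
        assert len(res.pairwise) == 3
        assert np.isfinite(res.anova_p)


class TestSpearman:
    def test_self_and_negation(self, rng):
        df = pd.DataFrame({"a": rng.standard_normal(30)})
        df["b"] = -df["a"]
        rho, _ = spearman_matrix(df, ["a", "b"])
        assert rho.loc["a", "a"] == 1.0
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_constructed_afe_strongly_correlated_with_sd1(self, rng):
        df = synthetic_cohort(rng)
        rho, p = spearman_matrix(df, ["sd1", "sd2", "afe"])
        assert rho.loc["sd1", "afe"] > 0.5
        assert p.loc["sd1", "afe"] < 0.001


class TestStandardizedRegression:
    def test_exact_single_term(self, rng):
        x = rng.standard_normal(50)
        df = pd.DataFrame({"y": 3 * x + 1, "x": x})
        rep = standardized_regression(df, "y", ["x"])
        beta, p = rep.terms["x"]
        assert beta == pytest.approx(1.0, abs=1e-10)
        assert rep.r2_adj == pytest.approx(1.0, abs=1e-10)

    def test_single_term_beta_equals_pearson(self, rng):
        x = rng.standard_normal(200)
        y = 0.4 * x + rng.standard_normal(200)
        df = pd.DataFrame({"y": y, "x": x})
        rep = standardized_regression(df, "y", ["x"])
        assert rep.terms["x"][0] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_null_design_near_zero_r2(self, rng):
        r2s, betas = [], []
        for _ in range(100):
            df = pd.DataFrame(
                {
                    "y": rng.standard_normal(500),
                    "x1": rng.standard_normal(500),
                    "x2": rng.standard_normal(500),
                }
            )
            rep = standardized_regression(df, "y", ["x1", "x2"])
            r2s.append(rep.r2_adj)
            betas.append(abs(rep.terms["x1"][0]))
        assert abs(np.mean(r2s)) <= 0.02
        assert np.mean(betas) < 0.1

    def test_duplicated_predictors_rejected(self, rng):
        x = rng.standard_normal(40)
        df = pd.DataFrame({"y": rng.standard_normal(40), "x1": x, "x2": x})
        with pytest.raises(ParameterError, match="collinear"):
            standardized_regression(df, "y", ["x1", "x2"])

    def test_vif_of_orthogonal_predictors_near_one(self, rng):
        x1 = rng.standard_normal(300)
        x2 = rng.standard_normal(300)
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # orthogonalize
        df = pd.DataFrame({"y": rng.standard_normal(300), "x1": x1, "x2": x2})
        rep = standardized_regression(df, "y", ["x1", "x2"])
        for v in rep.vif.values():
            assert v == pytest.approx(1.0, abs=0.02)

    def test_durbin_watson_near_two_for_independent_residuals(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(500), "x": rng.standard_normal(500)})
        rep = standardized_regression(df, "y", ["x"])
        assert 1.7 < rep.durbin_watson < 2.3

    def test_constant_term_rejected(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(20), "x": np.ones(20)})
        with pytest.raises(ParameterError, match="constant"):
            standardized_regression(df, "y", ["x"])


class TestTirModels:
    def test_sd2_dominates_cv(self, rng):
        df = synthetic_cohort(rng)
        rep = tir_models(df, "sd2")
        beta_sd2 = rep.terms["sd2"][0]
        beta_cv = rep.terms["cv_percent"][0]
        assert beta_sd2 < 0
        assert abs(beta_sd2) > abs(beta_cv)
        assert rep.terms["sd2"][1] < 0.001

    def test_index_equal_to_cv_rejected(self, rng):
        df = synthetic_cohort(rng)
        with pytest.raises(ParameterError):
            tir_models(df, "cv_percent")

    def test_all_noise_tir_nominal_false_positive_rate(self, rng):
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            df = synthetic_cohort(rng, n=60)
            df["tir_hours_per_day"] = rng.normal(15, 3, len(df))
            rep = tir_models(df, "sd2")
            hits += rep.terms["sd2"][1] < 0.05
        # binomial 3-sigma envelope around the nominal 5% rate
        assert hits / n_sims <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sims)

    def test_stepwise_keeps_forced_terms(self, rng):
        df = synthetic_cohort(rng)
        rep = tir_models(df, "sd2", stepwise=True)
        assert "sd2" in rep.terms and "cv_percent" in rep.terms

    def test_patients_only_drops_nd(self, rng):
        df = synthetic_cohort(rng)
        df.loc[df.index[:30], "group"] = "ND"
        rep_all = tir_models(df, "sd2", subjects="all")
        rep_pat = tir_models(df, "sd2", subjects="patients")
        assert rep_pat.n == rep_all.n - 30

    def test_stepwise_forward_recovers_signal(self, rng):
        df = synthetic_cohort(rng)
        df["tir_hours_per_day"] = 20 - 3 * (df["bmi"] - 28) / 4 + rng.normal(0, 0.3, len(df))
        selected = stepwise_forward(df, "tir_hours_per_day", list(CORE_MODEL_TERMS))
        assert "bmi" in selected


class TestPaired:
    def test_identical_tables_zero_difference(self, rng):
        df = pd.DataFrame({"subject_id": list("abcde"), "m": rng.standard_normal(5)})
        res = paired_before_after(df, df.copy(), "m")
        assert res.mean_difference == 0.0
        assert res.zero_variance

    def test_exact_shift_flagged_zero_variance(self, rng):
        before = pd.DataFrame({"subject_id": list("abcde"), "m": rng.standard_normal(5)})
        after = before.assign(m=before["m"] - 1.0)
        res = paired_before_after(before, after, "m")
        assert res.mean_difference == pytest.approx(-1.0)
        assert res.zero_variance

    def test_detects_real_change(self, rng):
        before = pd.DataFrame({"subject_id": range(30), "m": rng.normal(10, 1, 30)})
        after = before.assign(m=before["m"] - 2 + rng.normal(0, 0.5, 30))
        res = paired_before_after(before, after, "m")
        assert res.p_value < 0.001
        assert res.mean_difference < -1

    def test_mismatched_subjects_rejected(self):
        b = pd.DataFrame({"subject_id": ["a", "b"], "m": [1.0, 2.0]})
        a = pd.DataFrame({"subject_id": ["a", "c"], "m": [1.0, 2.0]})
        with pytest.raises(ParameterError):
            paired_before_after(b, a, "m")
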