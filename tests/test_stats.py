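"""Statistics battery: quantile/outlier rules, tests vs enumeration oracles,
hierarchical regression recovery, logistic closed forms, power calculators."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gmaxff.stats import (
    descriptive_table,
    hierarchical_linear_regression,
    kruskal_wallis,
    logistic_model,
    normality_gate,
    outlier_flags,
    posthoc_pairwise,
    power_delta_r2,
    quantiles,
    sample_size_two_group,
    subject_level,
    wilcoxon_paired,
)
from gmaxff.synthetic import CohortSpec, LinearFFModel, generate_cohort_table

from _oracles import kw_exact_p_oracle, kw_h_oracle, wilcoxon_exact_p_oracle


class TestQuantilesAndDescriptives:
    def test_linear_rule_on_one_to_eight(self):
        q1, med, q3 = quantiles(range(1, 9), "linear")
        assert (q1, med, q3) == (2.75, 4.5, 6.25)

    def test_hinges_rule_on_one_to_eight(self):
        q1, med, q3 = quantiles(range(1, 9), "hinges")
        assert (q1, med, q3) == (2.5, 4.5, 6.5)

    def test_constant_vector_summary(self):
        df = pd.DataFrame({"group": ["Low"] * 5, "sex": ["male"] * 5, "ff_pct": 7.0})
        out = descriptive_table(df, healthy_pooled=False)
        row = out[out["sex"] == "All"].iloc[0]
        assert row["mean"] == row["median"] == 7.0
        assert row["sd"] == 0.0 and row["iqr"] == 0.0

    def test_layout_has_sex_and_pooled_rows(self):
        table, _ = generate_cohort_table(CohortSpec(seed=0))
        out = descriptive_table(subject_level(table))
        assert set(out["sex"]) == {"Male", "Female", "All"}
        assert "All healthy" in set(out["group"])
        n_all = out[(out["group"] == "All healthy") & (out["sex"] == "All")]["n"].iloc[0]
        assert n_all == 51


class TestNormalityGate:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])

    def test_calibrated_under_normal_null(self, rng):
        rejections = sum(
            normality_gate(rng.normal(size=50)).p_value < 0.05 for _ in range(200)
        )
        assert rejections / 200 <= 0.12

    def test_power_against_lognormal_skew(self, rng):
        rejections = sum(
            normality_gate(rng.lognormal(0, 1, size=50)).p_value < 0.05
            for _ in range(100)
        )
        assert rejections / 100 > 0.5


class TestKruskalWallis:
    def test_h_matches_hand_ranking(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kw_h_oracle(groups), abs=1e-12)

    @pytest.mark.parametrize(
        "groups",
        [
            [[1, 2, 3], [4, 5, 6], [7, 8, 9]],
            [[1.0, 1.0, 2.0], [3.0, 4.0], [5.0, 1.0, 2.0]],  # ties across groups
            [[10, 12], [11, 13, 14], [9, 8]],
            [[1, 5], [2, 6], [3, 7], [4, 8]],
        ],
    )
    def test_exact_permutation_p_matches_enumeration_oracle(self, groups):
        res = kruskal_wallis(groups)
        assert "exact" in (res.note or "")
        assert res.p_value == pytest.approx(kw_exact_p_oracle(groups), abs=1e-12)

    def test_chi_square_p_close_to_exact_for_nine_obs(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        exact = kruskal_wallis(groups).p_value
        approx = kruskal_wallis(groups, exact_limit=0).p_value
        assert approx == pytest.approx(exact, abs=0.05)

    def test_identical_observations_flagged(self):
        res = kruskal_wallis([[3.0, 3.0], [3.0, 3.0, 3.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert "identical" in res.note

    def test_extreme_separation(self):
        res = kruskal_wallis([np.arange(10), np.arange(100, 110), np.arange(200, 210)])
        assert res.p_value < 1e-4

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestPosthocPairwise:
    def test_four_groups_give_six_pairs(self, rng):
        groups = [rng.normal(size=10) for _ in range(4)]
        assert len(posthoc_pairwise(groups)) == 6

    def test_only_shifted_group_rejects(self, rng):
        groups = [rng.normal(size=15) for _ in range(4)]
        groups[0] = groups[0] + 50.0
        results = posthoc_pairwise(groups, names=["a", "b", "c", "d"])
        for res in results:
            if "a " in res.name or "(a" in res.name:
                assert res.p_value < 0.05
            else:
                assert res.p_value > 0.05

    def test_identical_groups_do_not_reject(self):
        groups = [[5.0] * 6] * 3
        assert all(r.p_value > 0.99 for r in posthoc_pairwise(groups))


class TestWilcoxonPaired:
    def test_exact_p_matches_sign_enumeration(self):
        diffs = [1.0, -2.0, 3.0, -4.0, 5.0]
        res = wilcoxon_paired(np.array(diffs), np.zeros(5))
        assert res.p_value == pytest.approx(wilcoxon_exact_p_oracle(diffs), abs=1e-12)

    @pytest.mark.parametrize(
        "diffs",
        [[2.0, 4.0, -1.0, 8.0, -16.0, 32.0], [1.5, -0.5, 2.5, 3.5], [-1.0, -2.0, -3.0, 4.0, 5.0]],
    )
    def test_exact_agreement_on_small_samples(self, diffs):
        res = wilcoxon_paired(np.array(diffs), np.zeros(len(diffs)))
        assert res.p_value == pytest.approx(wilcoxon_exact_p_oracle(diffs), abs=1e-12)

    def test_equal_sides_degenerate(self):
        res = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.effect == 0.0

    def test_reports_median_paired_difference(self):
        res = wilcoxon_paired([10.0, 12.0, 15.0], [7.0, 9.0, 11.0])
        assert res.effect == pytest.approx(3.0)

    def test_injected_side_offset_detected(self):
        spec = CohortSpec(seed=11)  # default linear model: right side -3.0
        table, _ = generate_cohort_table(spec)
        healthy = table[table["group"] != "Pain"]
        wide = healthy.pivot_table(index="subject_id", columns="side", values="ff_pct")
        res = wilcoxon_paired(wide["left"], wide["right"])
        assert res.p_value < 0.01
        assert res.effect == pytest.approx(3.0, abs=1.5)


class TestOutlierRule:
    def test_threshold_from_hand_quartiles(self):
        values = [10, 12, 14, 16, 18, 20]
        # linear interpolation: Q1 = 12.5, Q3 = 17.5, fence = 17.5 + 1.5*5 = 25
        thr, flags = outlier_flags(values)
        assert thr == pytest.approx(25.0)
        assert not flags.any()

    def test_constant_vector_no_flags(self):
        thr, flags = outlier_flags([4.0] * 6)
        assert thr == 4.0 and not flags.any()

    def test_value_exactly_at_threshold_not_flagged(self):
        values = [10.0, 12.0, 14.0, 16.0, 18.0, 20.0, 25.0]
        thr, flags = outlier_flags(values)
        vals = np.asarray(values)
        assert not flags[vals == thr].any()

    def test_clear_outlier_flagged(self):
        thr, flags = outlier_flags([10, 11, 12, 13, 14, 60])
        assert flags.sum() == 1

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            outlier_flags([1.0, 2.0, 3.0])


class TestHierarchicalRegression:
    def test_noiseless_recovery_is_exact(self):
        spec = CohortSpec(ff_model=LinearFFModel(sd_eps=0.0), seed=3)
        table, truth = generate_cohort_table(spec)
        fit = hierarchical_linear_regression(table)
        assert fit.r2_final == pytest.approx(1.0, abs=1e-12)
        assert fit.retained == ["gender", "bmi", "age", "activity", "side"]
        coefs = fit.final_coefficients["coef"]
        assert coefs["male"] == pytest.approx(truth["beta_male"], abs=1e-8)
        assert coefs["bmi"] == pytest.approx(truth["beta_bmi"], abs=1e-8)
        assert coefs["age_years"] == pytest.approx(truth["beta_age"], abs=1e-8)
        assert coefs["side_right"] == pytest.approx(truth["beta_side_right"], abs=1e-8)
        assert coefs["C(group, Treatment(reference='High'))[T.Pain]"] == pytest.approx(
            truth["beta_group"]["Pain"], abs=1e-8
        )

    def test_cumulative_r2_non_decreasing_and_consistent(self):
        table, _ = generate_cohort_table(CohortSpec(seed=9))
        fit = hierarchical_linear_regression(table)
        prev = 0.0
        for step in fit.steps:
            if step.retained:
                assert step.cumulative_r2 >= prev - 1e-12
                assert step.delta_r2 == pytest.approx(step.cumulative_r2 - prev, abs=1e-10)
                prev = step.cumulative_r2

    def test_null_predictor_rarely_retained(self, rng):
        table, _ = generate_cohort_table(
            CohortSpec(ff_model=LinearFFModel(beta_age=0.0, sd_eps=4.0), seed=1)
        )
        retained = 0
        for _ in range(40):
            t = table.copy()
            t["age_years"] = rng.permutation(t["age_years"].to_numpy())
            fit = hierarchical_linear_regression(t, entry_order=("gender", "bmi", "age"))
            retained += "age" in fit.retained
        assert retained <= 7  # ~alpha-level exclusion failure rate

    def test_rank_deficient_design_reported(self):
        table, _ = generate_cohort_table(CohortSpec(seed=2))
        table = table[table["group"] != "Pain"].copy()
        table["ohs_score"] = np.nan  # OHS column collapses onto the intercept
        with pytest.raises(ValueError, match="rank"):
            hierarchical_linear_regression(table, entry_order=("gender", "ohs"))

    def test_unknown_predictor_rejected(self):
        table, _ = generate_cohort_table(CohortSpec(seed=2))
        with pytest.raises(ValueError, match="unknown"):
            hierarchical_linear_regression(table, entry_order=("gender", "shoe_size"))


class TestLogisticModel:
    def test_single_binary_predictor_equals_cross_product_ratio(self):
        # gender counts: Pain M=7/F=12 vs healthy M=31/F=20
        table, _ = generate_cohort_table(CohortSpec(seed=0))
        fit = logistic_model(table, outcome="pain_vs_healthy", predictors=["male"])
        expected = (7 * 20) / (12 * 31)
        assert fit.table.loc["male", "odds_ratio"] == pytest.approx(expected, rel=1e-6)

    def test_ci_brackets_or(self):
        table, _ = generate_cohort_table(CohortSpec(seed=4))
        fit = logistic_model(table, outcome="active_vs_not")
        t = fit.table
        assert (t["ci_low"] <= t["odds_ratio"]).all()
        assert (t["odds_ratio"] <= t["ci_high"]).all()
        assert (t["odds_ratio"] > 0).all()

    def test_null_covariate_or_centers_on_one(self, rng):
        covered = 0
        reps = 200
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "subject_id": range(60),
                    "group": ["Pain"] * 30 + ["High"] * 30,
                    "x": rng.normal(size=60),
                }
            )
            fit = logistic_model(df, outcome="pain_vs_healthy", predictors=["x"])
            row = fit.table.loc["x"]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered / reps > 0.88  # nominal 95% coverage

    def test_ff_separation_between_activity_classes_detected(self):
        spec = CohortSpec(seed=6)  # pain/low sit well above mid/high in FF
        table, _ = generate_cohort_table(spec)
        fit = logistic_model(table, outcome="active_vs_not")
        row = fit.table.loc["ff_pct"]
        assert row["odds_ratio"] > 1.0 and row["ci_low"] > 1.0

    def test_complete_separation_reported(self):
        df = pd.DataFrame(
            {
                "subject_id": range(20),
                "group": ["Pain"] * 10 + ["High"] * 10,
                "x": list(range(10)) + list(range(100, 110)),
            }
        )
        with pytest.raises(ValueError, match="[Ss]eparation"):
            logistic_model(df, outcome="pain_vs_healthy", predictors=["x"])

    def test_unknown_outcome(self):
        table, _ = generate_cohort_table(CohortSpec(seed=0))
        with pytest.raises(ValueError, match="outcome"):
            logistic_model(table, outcome="bogus")


class TestPowerAndSampleSize:
    def test_two_group_formula_values(self):
        # 2 (z_{0.975} + z_{0.8})^2 (4/3)^2 = 27.9 -> 28 per group
        assert sample_size_two_group(delta=3, sd=4, power=0.8, alpha=0.05) == 28
        assert sample_size_two_group(delta=3, sd=4, power=0.8, alpha=0.05, tails=1) == 22

    def test_huge_effect_floors_at_two(self):
        assert sample_size_two_group(delta=1000, sd=1) == 2

    def test_t_refinement_never_below_normal_approximation(self):
        n_z = sample_size_two_group(3, 4)
        n_t = sample_size_two_group(3, 4, use_t=True)
        assert n_t >= n_z

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_size_two_group(0, 4)
        with pytest.raises(ValueError):
            sample_size_two_group(3, 4, power=1.0)

    def test_zero_effect_power_equals_alpha(self):
        assert power_delta_r2(0.0, 0.0, 100, 3, 7, alpha=0.05) == pytest.approx(0.05)

    def test_monotone_in_n_and_effect(self):
        ps_n = [power_delta_r2(0.08, 0.5, n, 3, 7) for n in (30, 60, 120, 240)]
        assert all(b > a for a, b in zip(ps_n, ps_n[1:]))
        ps_d = [power_delta_r2(d, 0.5, 80, 3, 7) for d in (0.02, 0.05, 0.1, 0.2)]
        assert all(b > a for a, b in zip(ps_d, ps_d[1:]))

    def test_matches_monte_carlo_partial_f_power(self, rng):
        # Orthonormalised design: X'X = n I so lambda = n * f^2 exactly
        n, p, q = 60, 5, 2  # p predictors, last q form the tested block
        delta_r2, r2_full = 0.13, 0.13
        f2 = delta_r2 / (1 - r2_full)
        X = rng.normal(size=(n, p))
        Q, _ = np.linalg.qr(X - X.mean(0))
        X = Q * np.sqrt(n)
        beta = np.zeros(p)
        beta[-q:] = np.sqrt(f2 / q)
        Xf = np.column_stack([np.ones(n), X])
        Xr = Xf[:, : 1 + p - q]
        hat_f = np.linalg.pinv(Xf)
        hat_r = np.linalg.pinv(Xr)
        df2 = n - p - 1
        crit = sps.f.isf(0.05, q, df2)
        rejects = 0
        reps = 4000
        for _ in range(reps):
            y = Xf[:, 1:] @ beta + rng.normal(size=n)
            rf = y - Xf @ (hat_f @ y)
            rr = y - Xr @ (hat_r @ y)
            fstat = ((rr @ rr - rf @ rf) / q) / ((rf @ rf) / df2)
            rejects += fstat > crit
        mc = rejects / reps
        se = np.sqrt(mc * (1 - mc) / reps)
        analytic = power_delta_r2(delta_r2, r2_full, n, q, p)
        assert abs(analytic - mc) < 2.5 * se + 1e-9

    def test_invalid_degrees_of_freedom(self):
        with pytest.raises(ValueError):
            power_delta_r2(0.1, 0.3, 8, 3, 7)
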