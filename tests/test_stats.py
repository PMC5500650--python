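"""Group-inference layer: t/F tests, partial correlations, gates, outliers."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netfalff.errors import DataError, DegenerateInputError
from netfalff.stats import (
    ancova_group_f,
    conflict_effect,
    conflict_effect_from_trials,
    flag_outliers,
    network_group_table,
    normality_gate_log_transform,
    partial_correlation,
    two_sample_t,
)


class TestConflictEffect:
    def test_arithmetic(self):
        assert conflict_effect(800, 650) == 150
        assert conflict_effect(650, 650) == 0

    def test_trial_table_aggregation_matches_flat_oracle(self, rng):
        rts = rng.uniform(400, 900, 60)
        cond = np.array(["incongruent", "congruent"] * 30)
        trials = pd.DataFrame({"rt": rts, "condition": cond})
        expected = rts[cond == "incongruent"].mean() - rts[cond == "congruent"].mean()
        assert conflict_effect_from_trials(trials) == pytest.approx(expected)


class TestTwoSampleT:
    def test_education_summaries_reproduce_reported_p(self):
        t, p = two_sample_t((12.2, 2.9, 22), (11.8, 2.9, 18))
        assert t == pytest.approx(0.434, abs=1e-3)
        assert p == pytest.approx(0.666, abs=2e-3)

    def test_identical_groups(self, rng):
        x = rng.standard_normal(10)
        t, p = two_sample_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_summary_path_equals_raw_path_and_scipy(self, rng):
        a = rng.standard_normal(15) + 0.3
        b = rng.standard_normal(12)
        t_raw, p_raw = two_sample_t(a, b)
        t_sum, p_sum = two_sample_t(
            (a.mean(), a.std(ddof=1), 15), (b.mean(), b.std(ddof=1), 12)
        )
        assert t_raw == pytest.approx(t_sum, abs=1e-10)
        assert p_raw == pytest.approx(p_sum, abs=1e-10)
        ref = sps.ttest_ind(a, b)
        assert t_raw == pytest.approx(ref.statistic, abs=1e-10)
        assert p_raw == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            two_sample_t(np.full(5, 1.0), np.full(6, 1.0))


class TestAncova:
    def test_reduces_to_squared_t_without_covariate_effects(self, rng):
        n = 400
        g = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        y = rng.standard_normal(n) + (g == "B") * 0.3
        z = rng.standard_normal((n, 3))  # independent of y
        res = ancova_group_f(y, g, z)
        t, _ = two_sample_t(y[g == "B"], y[g == "A"])
        assert res.t_or_f == pytest.approx(t**2, rel=0.05)

    def test_matches_statsmodels_ols_f(self, rng):
        import statsmodels.api as sm

        n = 60
        g = np.array(["A", "B"] * (n // 2))
        z = rng.standard_normal((n, 2))
        y = 0.4 * (g == "B") + z @ [0.2, -0.1] + rng.standard_normal(n)
        res = ancova_group_f(y, g, z)
        X = sm.add_constant(np.column_stack([(g == "B").astype(float), z]))
        fit = sm.OLS(y, X).fit()
        # single-coefficient F equals the squared t of the group coefficient
        assert res.t_or_f == pytest.approx(fit.tvalues[1] ** 2, abs=1e-8)
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_singular_design_raises_with_context(self, rng):
        n = 30
        g = np.array(["A", "B"] * (n // 2))
        z = np.column_stack([(g == "B").astype(float)])  # duplicates the group column
        with pytest.raises(DataError, match="collinear"):
            ancova_group_f(rng.standard_normal(n), g, z, covariate_names=("dup",))

    def test_type_i_error_calibrated(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            g = np.array(["A"] * 22 + ["B"] * 18)
            y = rng.standard_normal(40)
            z = rng.standard_normal((40, 3))
            hits += ancova_group_f(y, g, z).p < 0.05
        assert abs(hits / reps - 0.05) < 0.03


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x, y = rng.standard_normal((2, 40))
        res = partial_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_planted_partial_r_recovered(self, rng):
        n = 500
        z = rng.standard_normal((n, 3))
        x = z @ [0.5, -0.3, 0.2] + rng.standard_normal(n)
        e = rng.standard_normal(n)
        rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
        y = z @ [0.1, 0.4, -0.2] + 0.5 * rx / rx.std() + np.sqrt(0.75) * e
        res = partial_correlation(x, y, z)
        assert 0.42 <= res.r <= 0.58

    def test_matches_explicit_residual_oracle_and_pingouin(self, rng):
        n = 50
        z = rng.standard_normal((n, 3))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        design = np.column_stack([np.ones(n), z])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        oracle = np.corrcoef(rx, ry)[0, 1]
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(oracle, abs=1e-10)
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame({"x": x, "y": y, "z0": z[:, 0], "z1": z[:, 1], "z2": z[:, 2]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z0", "z1", "z2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_invariant_to_affine_recoding_of_binary_covariate(self, rng):
        n = 40
        sex01 = rng.integers(0, 2, n).astype(float)
        z1 = np.column_stack([sex01, rng.standard_normal(n)])
        z2 = z1.copy()
        z2[:, 0] = 5.0 - 3.0 * z2[:, 0]  # affine recode
        x, y = rng.standard_normal((2, n))
        a = partial_correlation(x, y, z1)
        b = partial_correlation(x, y, z2)
        assert a.r == pytest.approx(b.r, abs=1e-10)


class TestNormalityGate:
    def test_lognormal_sample_triggers_and_usually_improves(self, rng):
        improved = 0
        triggered = 0
        for _ in range(200):
            v = np.exp(rng.standard_normal(22) * 0.8 + 2.0)
            rep = normality_gate_log_transform(v)
            if rep.transformed:
                triggered += 1
                improved += rep.shapiro_p_after > rep.shapiro_p_before
        assert triggered > 100
        assert improved / triggered >= 0.9

    def test_normal_sample_passes_untouched(self, rng):
        v = rng.standard_normal(200)
        rep = normality_gate_log_transform(v)
        if not rep.transformed:  # gate is stochastic; identity expected typically
            np.testing.assert_array_equal(rep.values, v)

    def test_log_base_does_not_change_downstream_correlation(self, rng):
        v = np.exp(rng.standard_normal(30) + 2)
        y = rng.standard_normal(30)
        r_ln = np.corrcoef(np.log(v), y)[0, 1]
        r_l10 = np.corrcoef(np.log10(v), y)[0, 1]
        assert r_ln == pytest.approx(r_l10, abs=1e-12)

    def test_nonpositive_values_error_when_triggered(self):
        v = np.concatenate([np.zeros(3), np.ones(3), np.full(16, 30.0)])
        with pytest.raises(DataError, match="offset"):
            normality_gate_log_transform(v)


class TestOutliers:
    def test_practice_intensity_outlier_flagged(self, rng):
        vals = np.concatenate([rng.normal(12, 1.5, 21), [30.0]])
        rep = flag_outliers(vals)
        assert rep.flags.sum() == 1 and rep.flags[-1]

    def test_all_equal_none_flagged(self):
        assert not flag_outliers(np.full(10, 3.0)).flags.any()

    def test_fences_match_independent_quantile_oracle(self, rng):
        vals = rng.standard_normal(101)
        rep = flag_outliers(vals, k=3.0)
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        assert rep.lo_fence == pytest.approx(q1 - 3 * (q3 - q1), abs=1e-12)
        assert rep.hi_fence == pytest.approx(q3 + 3 * (q3 - q1), abs=1e-12)


class TestGroupTable:
    def test_table_reports_both_statistics_and_covariates(self, rng):
        n = 24
        cohort = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": ["TCC"] * 12 + ["CTR"] * 12,
                "age": rng.uniform(40, 70, n),
                "sex": rng.choice(["M", "F"], n),
                "education": rng.uniform(8, 18, n),
            }
        )
        wide = pd.DataFrame(
            rng.uniform(0.3, 0.9, (n, 2)),
            columns=["ICN01", "ICN02"],
            index=cohort["subject_id"],
        )
        out = network_group_table(wide, cohort)
        assert set(out["network"]) == {"ICN01", "ICN02"}
        assert {"t", "p_t", "F", "p_F"} <= set(out.columns)
        assert (out["covariates"] == "age,sex,education").all()
        out_adj = network_group_table(wide, cohort, correction="bonferroni")
        assert (out_adj["p_F_adj"] >= out_adj["p_F"] - 1e-12).all()
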