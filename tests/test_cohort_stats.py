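import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from cdsvoice import cohort_stats as cs
from conftest import make_long_table


def brute_force_pearson(x, y):
    """Product-moment definition, written independently of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


class TestAggregate:
    def test_identical_rows_collapse_to_themselves(self):
        long = make_long_table(5, seed=1, within_sd=0.0)
        rec = cs.aggregate_mother_features(long)
        assert len(rec) == 5
        first = long[long.mother_id == "m000"].iloc[0]
        got = rec[rec.mother_id == "m000"].iloc[0]
        assert got["pitch_height"] == pytest.approx(first["pitch_height"])

    def test_mean_matches_hand_sum(self):
        long = make_long_table(3, seed=2, within_sd=5.0)
        rec = cs.aggregate_mother_features(long)
        for m in rec.mother_id:
            hand = long.loc[long.mother_id == m, "pitch_height"].sum() / 9
            assert rec.loc[rec.mother_id == m, "pitch_height"].iloc[0] == pytest.approx(hand)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            cs.aggregate_mother_features(pd.DataFrame())


class TestPearsonInference:
    def test_printed_inference_round_trip(self):
        """Any data realizing r = -0.38 at n = 50 must give t = -2.85 and
        Fisher CI [-0.60, -0.11] to two decimals."""
        x, y = _exact_r_data(-0.38, 50)
        res = cs.pearson_inference(x, y)
        assert res.r == pytest.approx(-0.38, abs=1e-9)
        assert res.t == pytest.approx(-2.85, abs=0.005)
        assert res.df == 48
        assert res.ci_low == pytest.approx(-0.60, abs=0.005)
        assert res.ci_high == pytest.approx(-0.11, abs=0.005)
        # the quoted r is itself rounded to 2 dp, so p carries ~1e-3 slack
        assert res.p == pytest.approx(0.007, abs=1e-3)

    def test_small_worked_example(self):
        res = cs.pearson_inference([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)
        assert res.t == pytest.approx(0.8 * np.sqrt(2) / np.sqrt(1 - 0.64), abs=1e-9)

    def test_perfect_correlation_handled(self):
        x = np.arange(10.0)
        res = cs.pearson_inference(x, x)
        assert res.r == 1.0 and res.ci_low == res.ci_high == 1.0 and res.p == 0.0

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            cs.pearson_inference(np.ones(10), np.arange(10.0))

    @settings(max_examples=50, deadline=None)
    @given(hst.integers(0, 2**31 - 1), hst.integers(5, 40))
    def test_matches_brute_force_and_scipy(self, seed, n):
        import scipy.stats as st

        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = cs.pearson_inference(x, y)
        assert res.r == pytest.approx(brute_force_pearson(x, y), abs=1e-12)
        ref = st.pearsonr(x, y)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_ci_matches_pingouin(self):
        """Independent oracle for the Fisher-z interval."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = cs.pearson_inference(x, y)
        ref = pingouin.corr(x, y)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        lo, hi = ref[ci_col].iloc[0]
        assert res.ci_low == pytest.approx(lo, abs=5e-3)
        assert res.ci_high == pytest.approx(hi, abs=5e-3)

    @settings(max_examples=60, deadline=None)
    @given(hst.integers(0, 2**31 - 1))
    def test_ci_excludes_zero_iff_significant(self, seed):
        """Fisher CI and t test agree on significance for the vast majority
        of draws (the tests differ slightly, so only near-threshold cases
        may disagree)."""
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=25), rng.normal(size=25)
        res = cs.pearson_inference(x, y)
        ci_excludes = res.ci_low > 0 or res.ci_high < 0
        if abs(res.p - 0.05) > 0.02:  # away from the boundary they must agree
            assert ci_excludes == (res.p < 0.05)


def _exact_r_data(r: float, n: int, seed: int = 0):
    """Construct vectors whose sample correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    e -= np.polyval(np.polyfit(x, e, 1), x)  # orthogonalize to x
    xz = (x - x.mean()) / x.std()
    ez = (e - e.mean()) / e.std()
    y = r * xz + np.sqrt(1 - r**2) * ez
    return x, y


class TestPartialCorrelation:
    def test_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        n = 20
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = -0.3 * z + rng.normal(size=n)
        res = cs.partial_correlation(x, y, z)
        # hand least squares then Pearson on residuals
        X = np.column_stack([np.ones(n), z])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.r == pytest.approx(brute_force_pearson(rx, ry), abs=1e-12)
        assert res.df == n - 3

    def test_independent_confound_leaves_r_unchanged(self):
        rng = np.random.default_rng(5)
        n = 5000
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # independent of both
        plain = cs.pearson_inference(x, y).r
        partial = cs.partial_correlation(x, y, z).r
        assert abs(plain - partial) < 0.05

    def test_collinear_outcome_raises(self):
        z = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            cs.partial_correlation(np.random.default_rng(0).normal(size=10), z.copy(), z)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "y", "z"])
        res = cs.partial_correlation(df.x, df.y, df.z)
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        p_col = "p-val" if "p-val" in ref.columns else "p_val"
        assert res.r == pytest.approx(ref["r"].iloc[0], abs=1e-10)
        assert res.p == pytest.approx(ref[p_col].iloc[0], abs=1e-6)


class TestFweAdjust:
    def test_printed_family_round_trip(self):
        assert cs.fwe_adjust([0.007, 0.86, 0.23, 0.59, 0.02])[0] == pytest.approx(0.035)

    def test_capped_at_one(self):
        assert cs.fwe_adjust([0.5] * 5)[0] == 1.0

    def test_single_test_unchanged(self):
        assert cs.fwe_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_statsmodels_bonferroni(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.04, 0.2, 0.7, 0.99])
        ref = multipletests(p, method="bonferroni")[1]
        assert np.allclose(cs.fwe_adjust(p), ref)

    def test_empty_family_raises(self):
        with pytest.raises(ValueError):
            cs.fwe_adjust([])


class TestBalancedFolds:
    def test_deterministic_under_seed(self, rng):
        x, y = np.random.default_rng(1).normal(size=(2, 48))
        a = cs.assign_balanced_folds(x, y, k=4, rng=np.random.default_rng(9))
        b = cs.assign_balanced_folds(x, y, k=4, rng=np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_fold_sizes_equal(self):
        x, y = np.random.default_rng(2).normal(size=(2, 48))
        labels = cs.assign_balanced_folds(x, y, k=4, rng=np.random.default_rng(0))
        assert sorted(np.bincount(labels)[1:]) == [12, 12, 12, 12]

    def test_posthoc_anova_satisfies_constraint(self):
        import scipy.stats as st

        x, y = np.random.default_rng(3).normal(size=(2, 50))
        labels = cs.assign_balanced_folds(x, y, k=4, rng=np.random.default_rng(1))
        groups_x = [x[labels == f] for f in range(1, 5)]
        groups_y = [y[labels == f] for f in range(1, 5)]
        assert st.f_oneway(*groups_x).pvalue > 0.50
        assert st.f_oneway(*groups_y).pvalue > 0.50

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            cs.assign_balanced_folds(np.arange(7.0), np.arange(7.0), k=4)


class TestCvPrediction:
    def test_noiseless_line_predicts_perfectly(self):
        x = np.random.default_rng(0).normal(size=40)
        y = 2 * x + 1
        res = cs.cv_prediction_r(x, y, reps=10, rng=np.random.default_rng(1))
        assert res.r_obs_pred == pytest.approx(1.0, abs=1e-9)

    def test_null_prediction_is_unskilled(self):
        """Out-of-sample prediction of pure noise has no average skill."""
        rs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=(2, 50))
            rs.append(cs.cv_prediction_r(x, y, reps=5, rng=rng).r_obs_pred)
        assert np.mean(rs) <= 0.05

    def test_constant_training_predictor_raises(self):
        x = np.ones(40)
        x[0] = 2.0
        with pytest.raises((ValueError, RuntimeError)):
            cs.cv_prediction_r(x, np.random.default_rng(0).normal(size=40), reps=2,
                               rng=np.random.default_rng(0))


class TestPermutationTest:
    def test_strong_signal_is_significant(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        y = x * np.sqrt(0.9) + rng.normal(size=50) * np.sqrt(0.1)
        res = cs.permutation_test_cv(x, y, reps=10, n_surrogates=199, rng=rng)
        assert res.p_perm <= 0.01

    def test_p_never_below_add_one_bound(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        y = 2 * x
        res = cs.permutation_test_cv(x, y, reps=5, n_surrogates=19, rng=rng)
        assert res.p_perm >= 1 / 20

    def test_zero_surrogates_rejected(self):
        with pytest.raises(ValueError):
            cs.permutation_test_cv(np.arange(20.0), np.arange(20.0), n_surrogates=0)


class TestMixedModels:
    def test_collapse_equivalence_with_identical_samples(self):
        """Nine identical utterances per mother: the mixed-model
        standardized slope equals the per-mother-mean Pearson r."""
        long = make_long_table(50, seed=7, within_sd=0.0)
        rec = cs.aggregate_mother_features(long)
        mm = cs.fit_random_intercept_model(long, "pitch_height")
        pe = cs.pearson_inference(rec["pitch_height"], rec["child_age"])
        assert mm.beta_std == pytest.approx(pe.r, abs=0.02)

    def test_one_sample_per_mother_matches_simple_regression(self):
        long = make_long_table(40, seed=8, within_sd=6.0).groupby("mother_id").head(1)
        mm = cs.fit_random_intercept_model(long, "pitch_height")
        pe = cs.pearson_inference(long["pitch_height"], long["child_age"])
        assert mm.beta_std == pytest.approx(pe.r, abs=1e-4)

    def test_variance_components_nonnegative_and_ci_ordered(self):
        long = make_long_table(30, seed=9, within_sd=6.0)
        mm = cs.fit_random_intercept_model(long, "pitch_height")
        assert mm.var_mother >= 0 and mm.var_resid >= 0
        assert mm.ci_low <= mm.beta_std <= mm.ci_high

    def test_parameter_recovery_beta_in_ci(self):
        """Generating at a known standardized slope, the fitted interval
        should cover it in most replicates."""
        hits = 0
        for seed in range(100):
            long = make_long_table(50, seed=100 + seed, slope=-2.4, noise_sd=14.0, within_sd=8.0)
            mm = cs.fit_random_intercept_model(long, "pitch_height")
            # true standardized slope implied by the generating law
            age_sd = long.groupby("mother_id")["child_age"].first().std()
            truth = -2.4 * age_sd / long["pitch_height"].std()
            hits += mm.ci_low <= truth <= mm.ci_high
        assert hits >= 90


class TestBrightnessWordModel:
    def test_no_word_specific_law_gives_null_interaction(self):
        long = make_long_table(50, seed=12, within_sd=5.0)
        res = cs.fit_brightness_word_model(long)
        assert res.interaction_effects
        assert max(abs(e["beta_std"]) for e in res.interaction_effects.values()) < 0.1

    def test_word_specific_slopes_detected(self):
        long = make_long_table(50, seed=13, within_sd=5.0)
        boost = (long["word"] == "keebudishawlt") * (-60.0) * (long["child_age"] - 12)
        long["brightness"] = long["brightness"] + boost
        res = cs.fit_brightness_word_model(long)
        assert min(e["p"] for e in res.interaction_effects.values()) < 0.05

    def test_reference_level_change_keeps_fitted_values(self):
        """Treatment coding is reference-dependent but the model is not."""
        import statsmodels.formula.api as smf

        long = make_long_table(20, seed=14, within_sd=5.0)
        data = pd.DataFrame(
            {
                "mother_id": long.mother_id,
                "y": (long.brightness - long.brightness.mean()) / long.brightness.std(),
                "age": (long.child_age - long.child_age.mean()) / long.child_age.std(),
                "word": long.word,
            }
        )
        fits = []
        for ref in ("keebudishawlt", "teebudishawlt"):
            res = smf.mixedlm(
                f"y ~ age * C(word, Treatment('{ref}'))", data, groups=data["mother_id"]
            ).fit(reml=True)
            fits.append(np.asarray(res.fittedvalues))
        assert np.max(np.abs(fits[0] - fits[1])) < 1e-6

    def test_single_word_redirects(self):
        long = make_long_table(10, seed=15)
        long = long[long.word == "keebudishawlt"]
        with pytest.raises(ValueError, match="fit_random_intercept_model"):
            cs.fit_brightness_word_model(long)


class TestRegressions:
    def test_single_predictor_beta_equals_r(self):
        rec = cs.aggregate_mother_features(make_long_table(50, seed=16, within_sd=4.0))
        table = cs.simultaneous_regression(rec, predictors=("pitch_height",))
        r = cs.pearson_inference(rec["pitch_height"], rec["child_age"]).r
        assert table.predictors["pitch_height"]["beta_std"] == pytest.approx(r, abs=1e-10)

    def test_orthogonal_predictors_recover_marginal_r(self):
        rng = np.random.default_rng(17)
        n = 64
        # center then orthonormalize five noise columns: predictors are
        # exactly mutually uncorrelated, so each multivariate standardized
        # beta must equal its marginal correlation
        g = rng.normal(size=(n, 5))
        g -= g.mean(axis=0)
        q, _ = np.linalg.qr(g)
        rec = pd.DataFrame(q, columns=cs.FEATURES)
        rec["child_age"] = q @ np.array([-0.4, 0.2, 0.0, 0.1, -0.1]) + 0.05 * rng.normal(size=n)
        table = cs.simultaneous_regression(rec)
        for f in cs.FEATURES:
            marginal = cs.pearson_inference(rec[f], rec["child_age"]).r
            assert table.predictors[f]["beta_std"] == pytest.approx(marginal, abs=1e-10)

    def test_exact_collinearity_names_pair(self):
        rec = cs.aggregate_mother_features(make_long_table(20, seed=18, within_sd=4.0))
        rec["brightness"] = rec["pitch_height"]
        with pytest.raises(ValueError, match="pitch_height.*brightness"):
            cs.simultaneous_regression(rec)

    def test_stepwise_base_round_trip_from_printed_r(self):
        """Data realizing r = -0.38, n = 50: base model adjusted R^2 = 0.13
        and F = 8.10 to two decimals."""
        x, y = _exact_r_data(-0.38, 50)
        rec = pd.DataFrame({"pitch_height": x, "child_age": y})
        for i, f in enumerate(("pitch_range", "duration", "amplitude", "brightness")):
            rec[f] = np.random.default_rng(300 + i).normal(size=50)
        table = cs.stepwise_model_comparison(rec)
        assert table.adj_r2 == pytest.approx(0.13, abs=0.005)
        assert table.f_stat == pytest.approx(8.10, abs=0.005)
        assert len(table.comparisons) == 4

    def test_pure_noise_additions_gain_nothing(self):
        deltas = []
        for seed in range(40):
            rng = np.random.default_rng(200 + seed)
            x = rng.normal(size=50)
            y = -0.38 * x + rng.normal(size=50)
            rec = pd.DataFrame(
                {
                    "pitch_height": x,
                    "child_age": y,
                    "pitch_range": rng.normal(size=50),
                    "duration": rng.normal(size=50),
                    "amplitude": rng.normal(size=50),
                    "brightness": rng.normal(size=50),
                }
            )
            table = cs.stepwise_model_comparison(rec, other_predictors=("pitch_range",))
            deltas.append(table.comparisons[0]["delta_adj_r2"])
        assert np.mean(deltas) <= 0.01

    def test_stepwise_nested_f_matches_statsmodels_anova(self):
        import statsmodels.api as sm
        from statsmodels.stats.anova import anova_lm

        rec = cs.aggregate_mother_features(make_long_table(40, seed=19, within_sd=4.0))
        table = cs.stepwise_model_comparison(rec, other_predictors=("brightness",))
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        base = sm.OLS(z(rec.child_age), sm.add_constant(pd.DataFrame({"ph": z(rec.pitch_height)}))).fit()
        ext = sm.OLS(
            z(rec.child_age),
            sm.add_constant(pd.DataFrame({"ph": z(rec.pitch_height), "br": z(rec.brightness)})),
        ).fit()
        ref = anova_lm(base, ext)
        assert table.comparisons[0]["F"] == pytest.approx(ref["F"].iloc[1], abs=1e-8)
        assert table.comparisons[0]["p"] == pytest.approx(ref["Pr(>F)"].iloc[1], abs=1e-8)


class TestSubgroupsAndExtrapolation:
    def test_partition_preserves_cohort(self):
        rec = cs.aggregate_mother_features(make_long_table(30, seed=20, within_sd=4.0))
        out = cs.subgroup_correlations(rec, "pitch_height", "child_age", "child_sex")
        total = sum(
            v.n for v in out.values() if isinstance(v, cs.CorrelationResult)
        )
        assert total == len(rec)

    def test_small_group_skipped(self):
        rec = cs.aggregate_mother_features(make_long_table(12, seed=21, within_sd=4.0))
        rec.loc[rec.index[:3], "child_sex"] = "girl"
        rec.loc[rec.index[3:], "child_sex"] = "boy"
        out = cs.subgroup_correlations(rec, "pitch_height", "child_age", "child_sex")
        assert "skipped" in out["girl"]

    def test_extrapolation_exact_line(self):
        age = np.linspace(8, 16, 20)
        rec = pd.DataFrame({"child_age": age, "pitch_height": 230 - 3 * age})
        assert cs.extrapolate_adult_pitch_age(rec, 175.0) == pytest.approx(55 / 3)

    def test_zero_slope_rejected(self):
        rec = pd.DataFrame({"child_age": np.linspace(8, 16, 20), "pitch_height": np.full(20, 188.0)})
        with pytest.raises(ValueError, match="slope"):
            cs.extrapolate_adult_pitch_age(rec, 175.0)
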