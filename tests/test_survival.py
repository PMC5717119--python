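import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import CoxPHFitter

from petprog.exceptions import DegenerateInputError, ValidationError
from petprog.survival import (
    NESTED_MODELS,
    CoxFit,
    PrognosticModel,
    aic,
    assign_quartiles,
    backward_eliminate,
    compare_models,
    events_per_variable,
    fit_cox,
    hazard_ratios,
    interaction_test,
    km_estimate,
    label_by_cutoffs,
    logrank_test,
    prognostic_score,
    transform_features,
    validate_model,
)
from petprog.synthetic import SimulationConfig, generate_cohort, simulate_survival
from petprog.experiments import model_table


def two_group_cohort(n, hr, seed, baseline=0.05):
    rng = np.random.default_rng(seed)
    group = (rng.random(n) < 0.5).astype(float)
    config = SimulationConfig(n=n, coefficients={}, baseline_hazard=baseline, seed=seed)
    os_months, event = simulate_survival(np.log(hr) * group, config, rng=rng)
    return pd.DataFrame(
        {"os_months": os_months, "event": event, "group": group}
    )


class TestTransforms:
    def test_log_columns_added_with_originals_kept(self):
        df = pd.DataFrame(
            {"id": ["a", "b"], "tlg": [np.e, 1.0], "hist_energy": [1.0, 0.5]}
        )
        out = transform_features(df)
        assert out["log_tlg"].tolist() == pytest.approx([1.0, 0.0])
        assert out["log_hist_energy"].iloc[0] == 0.0
        assert "tlg" in out.columns

    def test_non_positive_values_flagged_not_dropped(self):
        df = pd.DataFrame({"id": ["a", "b"], "tlg": [5.0, -1.0]})
        out = transform_features(df)
        assert len(out) == 2
        assert np.isnan(out["log_tlg"].iloc[1])
        assert out.attrs["transform_flags"]["log_tlg"] == ["b"]

    def test_log_reduces_right_skew(self):
        from scipy.stats import skew

        cohort = generate_cohort(SimulationConfig(n=302, seed=3))
        out = transform_features(cohort)
        assert skew(out["log_tlg"]) < skew(out["tlg"])


class TestCoxFit:
    def test_large_sample_recovery_of_true_hazard_ratio(self):
        fit = fit_cox(two_group_cohort(10_000, 2.0, seed=1), ["group"])
        assert abs(fit.beta[0] - np.log(2)) < 3 * fit.se[0]

    def test_agreement_with_lifelines_on_20_patient_fixture(self):
        df = two_group_cohort(20, 2.0, seed=4)
        df["x2"] = np.random.default_rng(5).standard_normal(20)
        fit = fit_cox(df, ["group", "x2"], min_events=5)
        ref = CoxPHFitter().fit(  # no ties here, so Breslow == Efron
            df, "os_months", "event", fit_options={"precision": 1e-11}
        )
        assert np.abs(fit.beta - ref.params_[["group", "x2"]].values).max() < 1e-6
        assert np.abs(fit.se - ref.standard_errors_[["group", "x2"]].values).max() < 1e-6
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-8)

    def test_efron_ties_agree_with_lifelines(self):
        df = two_group_cohort(150, 2.0, seed=6)
        df["os_months"] = np.ceil(df["os_months"])  # force heavy ties
        fit = fit_cox(df, ["group"], ties="efron")
        ref = CoxPHFitter().fit(df, "os_months", "event")
        assert abs(fit.beta[0] - ref.params_["group"]) < 1e-6

    def test_constant_covariate_degenerate(self):
        df = two_group_cohort(100, 1.0, seed=7)
        df["flat"] = 1.0
        with pytest.raises(DegenerateInputError, match="flat"):
            fit_cox(df, ["flat"])

    def test_too_few_events_rejected(self):
        df = two_group_cohort(30, 1.0, seed=8)
        df["event"] = 0
        df.loc[:3, "event"] = 1
        with pytest.raises(ValidationError, match="events"):
            fit_cox(df, ["group"])

    def test_empty_variable_list_gives_null_model(self):
        df = two_group_cohort(100, 2.0, seed=9)
        fit = fit_cox(df, [])
        assert fit.k == 0 and fit.loglik == fit.loglik_null


class TestEPV:
    def test_published_ratio(self):
        assert events_per_variable(232, 19) == 12.2

    def test_boundary_no_warning(self, recwarn):
        assert events_per_variable(100, 10) == 10.0
        assert not recwarn.list

    def test_below_threshold_warns(self):
        with pytest.warns(UserWarning, match="recommended minimum"):
            assert events_per_variable(90, 10) == 9.0


class TestHazardRatios:
    def test_hr_is_exp_beta_exactly(self):
        fit = fit_cox(two_group_cohort(500, 2.0, seed=10), ["group"])
        table = hazard_ratios(fit)
        assert table["hr"].iloc[0] == np.exp(fit.beta[0])
        lo, hi = table["ci_lower"].iloc[0], table["ci_upper"].iloc[0]
        assert np.log(lo) + np.log(hi) == pytest.approx(2 * fit.beta[0])


class TestPrognosticScore:
    def test_hand_arithmetic_on_published_weights(self):
        table = pd.DataFrame(
            {
                "stage_group": [3],
                "treatment": [1],
                "age": [67],
                "log_hist_energy": [-2.0],
                "log_tlg": [5.0],
                "hist_kurtosis": [3.0],
            }
        )
        score = prognostic_score(table, PrognosticModel())
        assert score.iloc[0] == pytest.approx(13.679)

    def test_all_zero_covariates_score_zero(self):
        table = pd.DataFrame(
            {v: [0.0] for v in PrognosticModel().weights}
        )
        assert prognostic_score(table, PrognosticModel()).iloc[0] == 0.0

    def test_derives_log_columns_from_raw_features(self):
        cohort = generate_cohort(SimulationConfig(n=20, seed=2))
        s1 = prognostic_score(cohort, PrognosticModel())
        s2 = prognostic_score(transform_features(cohort), PrognosticModel())
        assert np.allclose(s1, s2)


class TestQuartiles:
    def test_exact_split_of_eight(self):
        labels, cutoffs = assign_quartiles(np.arange(1.0, 9.0))
        assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]
        assert cutoffs == (2.0, 4.0, 6.0)

    def test_sizes_at_development_cohort_n(self):
        rng = np.random.default_rng(0)
        labels, _ = assign_quartiles(rng.standard_normal(302))
        sizes = [(labels == q).sum() for q in (1, 2, 3, 4)]
        assert sizes == [76, 76, 75, 75]

    def test_all_equal_scores_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            labels, _ = assign_quartiles(np.ones(20))
        assert set(labels) == {1}

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(50)
        a, _ = assign_quartiles(s)
        b, _ = assign_quartiles(s + 17.3)
        assert np.array_equal(a, b)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=25)
    def test_invariance_under_strictly_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.standard_normal(40)
        a, _ = assign_quartiles(s)
        b, _ = assign_quartiles(np.exp(0.5 * s) + 2 * s)
        assert np.array_equal(a, b)

    def test_nan_scores_get_label_zero(self):
        labels = label_by_cutoffs([0.1, np.nan, 5.0], (0.5, 1.0, 2.0))
        assert labels.tolist() == [1, 0, 4]


class TestKMLogrank:
    def test_product_limit_hand_example(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        surv = dict(zip(curve.times, curve.survival))
        assert surv[1.0] == pytest.approx(0.75)
        assert surv[2.0] == pytest.approx(0.5)
        assert surv[4.0] == pytest.approx(0.0, abs=1e-12)
        assert curve.median == 2.0

    def test_km_without_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 50).round(2)
        curve = km_estimate(t, np.ones(50))
        for time, s in zip(curve.times[1:], curve.survival[1:]):
            assert s == pytest.approx((t > time).mean(), abs=1e-12)

    def test_identical_groups_nonsignificant(self):
        t = np.tile(np.arange(1.0, 21.0), 2)
        e = np.ones(40)
        groups = np.repeat([0, 1], 20)
        res = logrank_test(t, e, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.99

    def test_separated_exponential_groups_significant(self):
        rng = np.random.default_rng(4)
        t = np.concatenate([rng.exponential(10, 300), rng.exponential(30, 300)])
        res = logrank_test(t, np.ones(600), np.repeat([0, 1], 300))
        assert res.df == 1 and res.p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestInteractionAndAIC:
    def test_interaction_df_is_one(self):
        cohort = generate_cohort(SimulationConfig(n=200, seed=5))
        score = prognostic_score(cohort, PrognosticModel())
        res = interaction_test(cohort, score)
        assert res.df == 1 and 0 <= res.p <= 1

    def test_aic_formula(self):
        fit = CoxFit(("a", "b", "c"), np.zeros(3), np.ones(3), -100.0, -110.0,
                     50, 30, "breslow", 3, True)
        assert aic(fit) == 206.0
        null = CoxFit((), np.zeros(0), np.zeros(0), -110.0, -110.0,
                      50, 30, "breslow", 0, True)
        assert aic(null) == 220.0

    def test_nested_aic_difference_identity(self):
        cohort = generate_cohort(SimulationConfig(n=250, seed=6))
        table = model_table(cohort)
        cmp = compare_models(table)
        m1 = cmp[cmp.model == "clinical"].iloc[0]
        m3 = cmp[cmp.model == "clinical+suv+texture"].iloc[0]
        dk, dll = m3.k - m1.k, m3.loglik - m1.loglik
        assert m3.aic - m1.aic == pytest.approx(2 * dk - 2 * dll, abs=1e-9)

    def test_nested_model_variable_sets(self):
        sets = list(NESTED_MODELS.values())
        assert set(sets[0]) < set(sets[1]) < set(sets[2])
        assert len(sets[2]) == 19


class TestBackwardElimination:
    def test_single_strong_variable_always_retained(self):
        for seed in range(5):
            df = two_group_cohort(250, 5.0, seed=seed)
            df["noise"] = np.random.default_rng(seed + 50).standard_normal(250)
            res = backward_eliminate(df, ["group", "noise"])
            assert "group" in res.fit.variables

    def test_removal_log_and_threshold(self):
        df = two_group_cohort(300, 3.0, seed=30)
        rng = np.random.default_rng(31)
        df["n1"], df["n2"] = rng.standard_normal(300), rng.standard_normal(300)
        res = backward_eliminate(df, ["group", "n1", "n2"])
        removed = [v for v, _ in res.removed]
        assert set(removed) <= {"n1", "n2"}
        assert all(p > 0.05 for _, p in res.removed)

    def test_pure_noise_never_errors(self):
        rng = np.random.default_rng(32)
        df = two_group_cohort(150, 1.0, seed=33)
        for i in range(4):
            df[f"x{i}"] = rng.standard_normal(150)
        res = backward_eliminate(df, [f"x{i}" for i in range(4)])
        assert res.fit.converged


class TestValidation:
    def test_development_cohort_relabels_identically(self):
        cohort = generate_cohort(SimulationConfig(n=120, seed=8))
        model = PrognosticModel()
        scores = prognostic_score(cohort, model)
        labels, cutoffs = assign_quartiles(scores.to_numpy())
        frozen = model.with_cutoffs(cutoffs)
        report = validate_model(frozen, cohort)
        assert np.array_equal(report.labels, labels)
        assert report.n_missing_score == 0

    def test_missing_feature_flagged_and_counted(self):
        cohort = generate_cohort(SimulationConfig(n=120, seed=9))
        model = PrognosticModel()
        cutoffs = assign_quartiles(prognostic_score(cohort, model).to_numpy())[1]
        frozen = model.with_cutoffs(cutoffs)
        cohort.loc[cohort.index[:5], "tlg"] = -1.0  # untransformable
        report = validate_model(frozen, transform_features(cohort))
        assert report.n_missing_score == 5

    def test_null_validation_completes(self):
        cohort = generate_cohort(SimulationConfig(n=101, coefficients={}, seed=10))
        model = PrognosticModel()
        cutoffs = assign_quartiles(prognostic_score(cohort, model).to_numpy())[1]
        report = validate_model(model.with_cutoffs(cutoffs), cohort)
        assert set(report.km_by_group) == {1, 2, 3, 4}

    def test_model_roundtrips_through_json(self, tmp_path):
        model = PrognosticModel().with_cutoffs((-1.0, 0.0, 1.5))
        model.save(tmp_path / "m.json")
        assert PrognosticModel.load(tmp_path / "m.json") == model
        with pytest.raises(ValidationError):
            PrognosticModel(cutoffs=(1.0, 1.0, 2.0))
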