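import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ncctrends import (
    PlatformTrialModel,
    ScenarioSpec,
    TrendSpec,
    fit_model,
    make_design,
    one_sided_p,
    simulate_trial,
    theta2_weighted,
)

from conftest import cell_means_frame


class TestNonContribution:
    """Methods whose estimate reduces to the concurrent-only difference
    ybar22 - ybar02: non-concurrent controls must not move the estimate."""

    @pytest.mark.parametrize("method", ["ALLTCI-step", "TC-step", "separate"])
    def test_estimate_is_concurrent_difference(self, canonical_dataset, method):
        ybar = cell_means_frame(canonical_dataset)
        res = fit_model(canonical_dataset, method)
        assert res.effect == pytest.approx(ybar[2, 1] - ybar[0, 1], abs=1e-10)

    def test_pooled_differs_under_a_trend(self, canonical_dataset):
        ybar = cell_means_frame(canonical_dataset)
        res = fit_model(canonical_dataset, "pooled")
        assert abs(res.effect - (ybar[2, 1] - ybar[0, 1])) > 1e-6


class TestClosedFormEquivalence:
    def test_alltc_step_matches_weighted_means(self, canonical_dataset, two_period_design):
        ybar = cell_means_frame(canonical_dataset)
        res = fit_model(canonical_dataset, "ALLTC-step")
        assert res.effect == pytest.approx(
            theta2_weighted(ybar, two_period_design.n), abs=1e-10)


class TestAgainstStatsmodels:
    """Independent cross-check of the in-package OLS / IRLS fitters."""

    @pytest.mark.parametrize("method, formula", [
        ("ALLTC-step", "y ~ C(arm) + C(period)"),
        ("ALLTC-linear", "y ~ C(arm) + j"),
        ("ALLTCI-step", "y ~ C(arm) + C(period) + I((arm == 1) & (period == 2))"),
    ])
    def test_continuous_ols(self, canonical_dataset, method, formula):
        smf = pytest.importorskip("statsmodels.formula.api")
        res = fit_model(canonical_dataset, method)
        ref = smf.ols(formula, data=canonical_dataset).fit()
        assert res.effect == pytest.approx(ref.params["C(arm)[T.2]"], abs=1e-8)
        assert res.se == pytest.approx(ref.bse["C(arm)[T.2]"], abs=1e-8)
        t = ref.params["C(arm)[T.2]"] / ref.bse["C(arm)[T.2]"]
        assert res.pvalue == pytest.approx(stats.t.sf(t, ref.df_resid), abs=1e-10)

    def test_binary_logistic(self, canonical_binary_dataset):
        smf = pytest.importorskip("statsmodels.formula.api")
        res = fit_model(canonical_binary_dataset, "ALLTC-step")
        ref = smf.logit("y ~ C(arm) + C(period)",
                        data=canonical_binary_dataset).fit(disp=0)
        assert res.converged
        assert res.effect == pytest.approx(ref.params["C(arm)[T.2]"], abs=1e-6)
        assert res.se == pytest.approx(ref.bse["C(arm)[T.2]"], abs=1e-6)

    def test_pooled_and_separate_match_t_tests(self, canonical_dataset):
        df = canonical_dataset
        y2 = df.loc[df.arm == 2, "y"]
        y0_all = df.loc[df.arm == 0, "y"]
        y0_conc = df.loc[(df.arm == 0) & (df.period == 2), "y"]
        pooled = fit_model(df, "pooled")
        sep = fit_model(df, "separate")
        assert pooled.pvalue == pytest.approx(
            stats.ttest_ind(y2, y0_all, alternative="greater").pvalue, abs=1e-12)
        assert sep.pvalue == pytest.approx(
            stats.ttest_ind(y2, y0_conc, alternative="greater").pvalue, abs=1e-12)

    def test_welch_variant(self, canonical_dataset):
        df = canonical_dataset
        y2 = df.loc[df.arm == 2, "y"]
        y0 = df.loc[df.arm == 0, "y"]
        res = fit_model(df, "pooled", welch=True)
        ref = stats.ttest_ind(y2, y0, equal_var=False, alternative="greater")
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)


class TestDegenerateInputs:
    def test_constant_outcomes_give_zero_effect(self, two_period_design):
        from ncctrends import allocate

        alloc = allocate(two_period_design, "block", (4, 12), seed=1)
        df = alloc.to_frame().assign(y=3.0)
        for method in ("ALLTC-step", "ALLTCI-step", "TC-step", "ALLTC-linear",
                       "TC-linear", "pooled", "separate"):
            assert fit_model(df, method, endpoint="continuous").effect == pytest.approx(0.0, abs=1e-10)

    def test_missing_tested_arm_rejected(self, canonical_dataset):
        df = canonical_dataset[canonical_dataset.arm != 2]
        with pytest.raises(ValueError, match="absent"):
            fit_model(df, "ALLTC-step", target_arm=2)

    def test_zero_residual_df_rejected(self):
        df = pd.DataFrame({"arm": [0, 0, 2], "period": [1, 2, 2],
                           "y": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_model(df, "TC-step", endpoint="continuous")

    def test_separated_binary_fit_is_flagged_not_silent(self):
        df = pd.DataFrame({
            "arm": [0] * 20 + [2] * 20,
            "period": [1] * 10 + [2] * 10 + [2] * 20,
            "y": [0.0] * 20 + [1.0] * 20,
        })
        res = fit_model(df, "separate", endpoint="binary")
        assert not res.converged
        assert np.isnan(res.effect) and np.isnan(res.pvalue)
        assert res.reject is False


class TestLogisticRecovery:
    def test_parameters_recovered_at_large_n(self):
        m = 50_000
        d = make_design([[m, m], [m, m], [0, m]])
        sc = ScenarioSpec(design=d, trend=TrendSpec("step", 0.25), endpoint="binary",
                          p0=0.7, odds_ratios=(1.8, 1.8), allocation="simple",
                          block_sizes=None)
        res = fit_model(simulate_trial(sc, seed=12), "ALLTC-step")
        assert res.converged
        truth = {"eta0": np.log(0.7 / 0.3), "theta1": np.log(1.8),
                 "theta2": np.log(1.8), "nu2": 0.25}
        for name, val in truth.items():
            assert abs(res.params[name] - val) < 3 * res.bse[name]


class TestOneSidedP:
    def test_reference_values(self):
        assert one_sided_p(0.0, 1.0) == pytest.approx(0.5)
        assert one_sided_p(1.959964, 1.0) == pytest.approx(0.025, abs=1e-6)
        assert one_sided_p(-0.5, 1.0) > 0.5
        assert one_sided_p(2.0, 1.0, df=10) > one_sided_p(2.0, 1.0)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            one_sided_p(1.0, 0.0)


class TestInterface:
    def test_method_name_normalisation(self, canonical_dataset):
        a = fit_model(canonical_dataset, "ALLTC_step")
        b = fit_model(canonical_dataset, "alltc step")
        assert a.effect == b.effect and a.method == b.method == "ALLTC-step"

    def test_unknown_method_rejected(self, canonical_dataset):
        with pytest.raises(ValueError, match="unknown method"):
            fit_model(canonical_dataset, "bayesian-time-machine")

    def test_endpoint_inferred_from_outcomes(self, canonical_binary_dataset):
        df = canonical_binary_dataset.copy()
        df.attrs.clear()
        model = PlatformTrialModel(df, "ALLTC-step")
        assert model.endpoint == "binary"

    def test_from_csv_round_trip(self, tmp_path, canonical_dataset):
        from ncctrends import write_dataset

        path = tmp_path / "d.csv"
        write_dataset(canonical_dataset, path)
        res = PlatformTrialModel.from_csv(path, method="ALLTC-step").fit()
        assert res.effect == pytest.approx(
            fit_model(canonical_dataset, "ALLTC-step").effect)

    def test_summary_reports_test_and_flags_nonconvergence(self, canonical_dataset):
        text = fit_model(canonical_dataset, "ALLTC-step").summary()
        assert "ALLTC-step" in text and "theta2" in text and "one-sided" in text
        bad = pd.DataFrame({"arm": [0] * 5 + [2] * 5, "period": [2] * 10,
                            "y": [0.0] * 5 + [1.0] * 5})
        assert "NOT CONVERGE" in fit_model(bad, "separate", endpoint="binary").summary()

    def test_record_serialisation(self, canonical_dataset):
        rec = fit_model(canonical_dataset, "ALLTC-step").to_record()
        assert set(rec) == {"method", "estimate", "se", "p", "reject", "converged"}
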