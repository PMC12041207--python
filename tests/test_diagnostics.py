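import numpy as np
import pandas as pd
import pytest
from scipy import stats

from resorb import (
    DegenerateFitError,
    InsufficientDataError,
    SyntheticConfig,
    ValidationError,
    concentration_control_test,
    fit_loglog,
    leaf_records,
    limitation_control_test,
    one_sided_slope_p,
    pair_site_periods,
    simulate_transect,
    site_resorption_table,
    stoichiometry_control_test,
    test_slope_against,
)


def _site_tables(config):
    leaf_df, _, _ = simulate_transect(config)
    site_df, rep_df = pair_site_periods(leaf_records(leaf_df))
    return site_df, rep_df, site_resorption_table(site_df)


class TestFitLoglog:
    def test_identity_line(self):
        x = np.linspace(1, 10, 10)
        fit = fit_loglog(x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.df == 8

    def test_noiseless_power_law(self):
        x = np.linspace(0.5, 8, 12)
        y = 2.0 * x**1.5
        fit = fit_loglog(x, y)
        assert fit.slope == pytest.approx(1.5, abs=1e-12)
        assert fit.intercept == pytest.approx(np.log10(2.0), abs=1e-12)

    def test_non_positive_value_names_index(self):
        with pytest.raises(ValidationError, match="index 2"):
            fit_loglog([1.0, 2.0, -1.0, 3.0], [1.0, 2.0, 3.0, 4.0])

    def test_constant_predictor_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_loglog([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_loglog([1.0, 2.0], [1.0, 2.0])

    def test_mixed_mode_matches_ols_for_singleton_groups(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 5, 20)
        y = 1.7 * x**1.2 * 10 ** rng.normal(0, 0.05, 20)
        ols = fit_loglog(x, y, mode="site_means")
        mixed = fit_loglog(x, y, mode="mixed", groups=np.arange(20))
        assert mixed.slope == pytest.approx(ols.slope, abs=1e-12)
        assert mixed.slope_se == pytest.approx(ols.slope_se, abs=1e-12)

    def test_mixed_mode_recovers_slope_on_replicated_data(self):
        site_df, rep_df, _ = _site_tables(
            SyntheticConfig(seed=7, lambda_np=None, b_n=1.4, sigma_log=0.02)
        )
        fit = fit_loglog(rep_df["mature_n"], rep_df["sen_n"], mode="mixed",
                         groups=rep_df["site_id"])
        assert fit.mode == "mixed"
        assert fit.slope == pytest.approx(1.4, abs=0.15)

    def test_parameter_recovery_seed_averaged(self):
        # multiplicative log-normal noise leaves the log-log slope unbiased
        slopes = []
        for seed in range(100):
            cfg = SyntheticConfig(seed=seed, lambda_np=None, b_n=1.3,
                                  sigma_log=0.05, n_sites=30)
            site_df, _, _ = _site_tables(cfg)
            slopes.append(fit_loglog(site_df["mature_n"], site_df["sen_n"]).slope)
        assert 1.2 <= np.mean(slopes) <= 1.4


class TestSlopeAgainst:
    def test_null_equal_to_slope_gives_p_one(self):
        fit = fit_loglog(np.linspace(1, 10, 10), np.linspace(1, 10, 10) ** 1.0
                         * 10 ** np.random.default_rng(0).normal(0, 0.01, 10))
        out = test_slope_against(fit, fit.slope)
        assert out.p_slope_vs_null == pytest.approx(1.0)

    def test_hand_computed_t_and_p(self):
        from resorb.diagnostics import RegressionFit

        fit = RegressionFit(slope=0.79, intercept=0.0, slope_se=0.05, r2=0.8,
                            n=30, df=28, p_slope_zero=1e-6)
        out = test_slope_against(fit, 1.0)
        t = (0.79 - 1.0) / 0.05
        assert t == pytest.approx(-4.2)
        assert out.p_slope_vs_null == pytest.approx(2 * stats.t.sf(4.2, 28), rel=1e-12)
        assert out.p_slope_vs_null == pytest.approx(2.4e-4, rel=0.05)

    def test_zero_se_is_degenerate(self):
        from resorb.diagnostics import RegressionFit

        fit = RegressionFit(slope=1.5, intercept=0.0, slope_se=0.0, r2=1.0,
                            n=10, df=8, p_slope_zero=0.0)
        with pytest.raises(DegenerateFitError):
            test_slope_against(fit, 1.0)

    def test_p_shrinks_as_se_shrinks_for_wrong_null(self):
        from resorb.diagnostics import RegressionFit

        ps = []
        for se in (0.2, 0.05, 0.01):
            fit = RegressionFit(slope=1.5, intercept=0.0, slope_se=se, r2=1.0,
                                n=30, df=28, p_slope_zero=0.0)
            ps.append(test_slope_against(fit, 1.0).p_slope_vs_null)
        assert ps[0] > ps[1] > ps[2]

    def test_one_sided_halves_two_sided_in_the_observed_direction(self):
        from resorb.diagnostics import RegressionFit

        fit = RegressionFit(slope=1.3, intercept=0.0, slope_se=0.1, r2=0.9,
                            n=30, df=28, p_slope_zero=1e-8)
        two = test_slope_against(fit, 1.0).p_slope_vs_null
        assert one_sided_slope_p(fit, 1.0, "greater") == pytest.approx(two / 2)
        assert one_sided_slope_p(fit, 1.0, "less") == pytest.approx(1 - two / 2)


class TestConcentrationControl:
    def test_noiseless_b_above_one_supported(self):
        cfg = SyntheticConfig(seed=1, lambda_np=None, b_n=1.5, a_n=0.05,
                              sigma_log=0.0, rep_sigma_log=0.0, tradeoff_slope=0.0)
        site_df, rep_df, _ = _site_tables(cfg)
        v = concentration_control_test(site_df, "N")
        assert v.supported
        assert v.evidence["fit"]["slope"] == pytest.approx(1.5, abs=1e-9)

    def test_noiseless_b_equal_one_not_supported(self):
        cfg = SyntheticConfig(seed=1, lambda_np=None, b_n=1.0, a_n=0.4,
                              sigma_log=0.0, rep_sigma_log=0.0, tradeoff_slope=0.0)
        site_df, rep_df, _ = _site_tables(cfg)
        v = concentration_control_test(site_df, "N")
        assert not v.supported

    def test_false_support_rate_under_independence(self):
        # senesced independent of mature: the verdict requires a significant
        # regression, so false support stays near the nominal level
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(100):
            site_df = pd.DataFrame({
                "site_id": [f"S{i}" for i in range(30)],
                "mature_n": 10 ** rng.normal(1.3, 0.1, 30),
                "sen_n": 10 ** rng.normal(0.9, 0.1, 30),
                "mature_p": 1.5, "sen_p": 0.4,
            })
            if concentration_control_test(site_df, "N").supported:
                hits += 1
        assert hits / 100 <= 0.05 + 0.03


class TestStoichiometryControl:
    def test_lambda_one_generator_supported(self):
        cfg = SyntheticConfig(seed=3, lambda_np=1.0, eps_np=0.78, sigma_log=0.01,
                              tradeoff_slope=0.0)
        _, _, site_res = _site_tables(cfg)
        v = stoichiometry_control_test(site_res)
        assert v.supported
        assert v.evidence["nre_pre_r"] > 0

    def test_shuffled_efficiencies_rarely_supported(self):
        cfg = SyntheticConfig(seed=3, lambda_np=1.0, eps_np=0.78, sigma_log=0.01,
                              tradeoff_slope=0.0)
        _, _, site_res = _site_tables(cfg)
        rng = np.random.default_rng(99)
        hits = 0
        n_shuffles = 100
        for _ in range(n_shuffles):
            shuffled = site_res.copy()
            shuffled["pre"] = rng.permutation(shuffled["pre"].to_numpy())
            shuffled["resorbed_np"] = rng.permutation(shuffled["resorbed_np"].to_numpy())
            if stoichiometry_control_test(shuffled).supported:
                hits += 1
        assert hits / n_shuffles <= 0.05

    def test_two_valid_sites_insufficient(self):
        site_res = pd.DataFrame({
            "site_id": ["A", "B", "C"],
            "nre": [50.0, 55.0, 60.0], "pre": [70.0, 72.0, 74.0],
            "resorbed_np": [10.0, 11.0, np.nan],
            "mature_np": [12.0, 13.0, 14.0],
        })
        with pytest.raises(InsufficientDataError):
            stoichiometry_control_test(site_res)


class TestLimitationControl:
    def test_noiseless_lambda_recovered_exactly(self):
        cfg = SyntheticConfig(seed=2, lambda_np=0.79, sigma_log=0.0,
                              rep_sigma_log=0.0, tradeoff_slope=0.0)
        _, _, site_res = _site_tables(cfg)
        v = limitation_control_test(site_res)
        assert v.evidence["fit"]["slope"] == pytest.approx(0.79, abs=1e-9)
        assert v.supported

    def test_noiseless_lambda_one_not_supported(self):
        cfg = SyntheticConfig(seed=2, lambda_np=1.0, eps_np=0.78, sigma_log=0.0,
                              rep_sigma_log=0.0, tradeoff_slope=0.0)
        _, _, site_res = _site_tables(cfg)
        assert not limitation_control_test(site_res).supported

    def test_exponent_consistency_between_ratio_fits(self):
        # when resorbed N:P = eps * (leaf N:P)^lambda holds exactly, the
        # efficiency-ratio fit NRE:PRE ~ leaf N:P recovers lambda - 1
        cfg = SyntheticConfig(seed=6, lambda_np=0.8, sigma_log=0.0,
                              rep_sigma_log=0.0, tradeoff_slope=0.0)
        _, _, site_res = _site_tables(cfg)
        lam = fit_loglog(site_res["mature_np"], site_res["resorbed_np"]).slope
        eff_ratio = site_res["nre"] / site_res["pre"]
        lam_minus_1 = fit_loglog(site_res["mature_np"], eff_ratio).slope
        assert lam_minus_1 == pytest.approx(lam - 1.0, abs=1e-9)


class TestVerdictInvariance:
    def test_verdicts_invariant_to_relabeling_and_row_order(self, default_site_tables):
        site_df, _, site_res = default_site_tables
        base = limitation_control_test(site_res)
        perm = site_res.sample(frac=1.0, random_state=8).reset_index(drop=True)
        perm["site_id"] = [f"X{i}" for i in range(len(perm))]
        shuffled = limitation_control_test(perm)
        assert shuffled.supported == base.supported
        assert shuffled.evidence["fit"]["slope"] == pytest.approx(
            base.evidence["fit"]["slope"], abs=1e-12
        )
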