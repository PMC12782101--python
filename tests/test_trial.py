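import numpy as np
import pytest

from cvrkit import (
    DESIGN_CI,
    DESIGN_CU,
    MetricReport,
    TrialDesign,
    bootstrap_ci,
    detectable_effect,
    group_separation,
    percentage_error,
    sample_size_estimate,
    sse_confint,
)
from cvrkit.model import fit_lmm
from cvrkit.trial import simulate_trial_power, slope_variance


class TestTrialDesign:
    def test_defaults_match_trial_configurations(self):
        assert DESIGN_CI.length_years == 1.5  # 78 weeks
        assert DESIGN_CU.length_years == 4.5  # 234 weeks
        assert DESIGN_CI.power == 0.80
        assert DESIGN_CI.alpha == 0.05
        assert DESIGN_CI.pct_change == 0.20
        assert DESIGN_CI.visit_times == (0.0, 1.5)
        assert DESIGN_CI.time_ss == pytest.approx(1.5**2 / 2)

    @pytest.mark.parametrize(
        "bad",
        [dict(power=0.0), dict(power=1.0), dict(alpha=0.0),
         dict(pct_change=0.0), dict(length_years=-1.0)],
    )
    def test_invalid_designs_rejected(self, bad):
        with pytest.raises(ValueError):
            TrialDesign(**bad)


class TestSampleSize:
    def test_worked_example_in_week_units(self, stub_fit_factory):
        """beta=0.0005/wk, sd(b1)=0.001/wk, sigma_e=0.05, T=78wk -> ~2860
        per arm (closed form; validated independently by the Monte-Carlo
        power simulation below)."""
        wk = 52.0  # express weekly parameters per year
        fit = stub_fit_factory(
            slope=0.0005 * wk, var_b1=(0.001 * wk) ** 2, sigma=0.05
        )
        raw = sample_size_estimate(fit, DESIGN_CI, ceiling=False)
        assert raw == pytest.approx(2859.8, abs=0.5)
        assert sample_size_estimate(fit, DESIGN_CI) == 2860

    def test_quadratic_scaling_in_effect_size(self, stub_fit_factory):
        fit = stub_fit_factory()
        n1 = sample_size_estimate(fit, TrialDesign(pct_change=0.2),
                                  ceiling=False)
        n2 = sample_size_estimate(fit, TrialDesign(pct_change=0.4),
                                  ceiling=False)
        assert n1 / n2 == pytest.approx(4.0, rel=1e-12)

    def test_longer_trials_need_fewer_subjects(self, stub_fit_factory):
        fit = stub_fit_factory()
        lengths = [1.0, 1.5, 2.0, 3.0, 4.5, 6.0]
        ns = [sample_size_estimate(fit, TrialDesign(length_years=T),
                                   ceiling=False) for T in lengths]
        assert all(a > b for a, b in zip(ns, ns[1:]))
        # approximately inverse relationship: log-log slope in (-2, -1)
        slope = np.polyfit(np.log(lengths), np.log(ns), 1)[0]
        assert -2.0 < slope < -1.0

    def test_zero_slope_rejected(self, stub_fit_factory):
        with pytest.raises(ValueError, match="zero"):
            sample_size_estimate(stub_fit_factory(slope=0.0), DESIGN_CI)

    def test_zero_variance_returns_one_with_warning(self, stub_fit_factory):
        fit = stub_fit_factory(var_b1=0.0, sigma=0.0)
        with pytest.warns(UserWarning, match="n = 1"):
            assert sample_size_estimate(fit, DESIGN_CI) == 1.0

    def test_nonconverged_fit_rejected(self, stub_fit_factory):
        with pytest.raises(RuntimeError, match="converged"):
            sample_size_estimate(stub_fit_factory(converged=False), DESIGN_CI)


class TestPercentageError:
    def test_zero_residual_sd_gives_zero(self, stub_fit_factory):
        assert percentage_error(stub_fit_factory(resid_sd=0.0)) == 0.0

    def test_exact_closed_form(self, stub_fit_factory):
        fit = stub_fit_factory(resid_sd=float(np.log(1.05)))
        assert percentage_error(fit) == pytest.approx(5.0, abs=1e-12)

    def test_empirical_variant_uses_residual_vector(self, stub_fit_factory):
        fit = stub_fit_factory(resid_sd=float(np.log(1.05)))
        assert percentage_error(fit, empirical=True) == pytest.approx(5.0,
                                                                      rel=1e-9)

    def test_generator_truth_recovered_at_scale(self, two_region_atlas):
        """A 1000-subject cohort generated with residual sd 0.0175 (and no
        shared scan-scale noise) yields a percentage error of 1.75 +- 0.15."""
        from cvrkit import CohortConfig, default_region_params, generate_cohort
        from cvrkit.biomarkers import column_ratio

        params = default_region_params(two_region_atlas, sigma_e=0.0175)
        cfg = CohortConfig(n_subjects=1000, seed=77, region_params=params,
                           sd_visit_scale=0.0)
        table = generate_cohort(cfg, two_region_atlas)
        fit = fit_lmm(column_ratio(table, "hippocampus", "icv"))
        assert percentage_error(fit) == pytest.approx(1.75, abs=0.15)

    def test_scale_invariance(self, hv_series):
        fit0 = fit_lmm(hv_series)
        fit1 = fit_lmm(hv_series.assign(value=hv_series["value"] * 11.0))
        assert percentage_error(fit1) == pytest.approx(percentage_error(fit0),
                                                       rel=1e-5)


class TestGroupSeparation:
    def test_reads_the_wald_t_of_the_slope_interactions(self, stub_fit_factory):
        fit = stub_fit_factory(t_ab=2.5, t_dx=-1.2)
        assert group_separation(fit, "AB") == 2.5
        assert group_separation(fit, "DX") == -1.2

    def test_zero_estimate_with_positive_se_gives_t_zero(self, stub_fit_factory):
        fit = stub_fit_factory(t_ab=0.0)
        assert group_separation(fit, "AB") == 0.0

    def test_absent_term_and_bad_selector_rejected(self, hv_series):
        reduced = fit_lmm(hv_series[hv_series["AB"] == 1], include_ab=False,
                          include_dx=True)
        with pytest.raises(ValueError, match="time:AB"):
            group_separation(reduced, "AB")
        with pytest.raises(ValueError, match="'AB' or 'DX'"):
            group_separation(reduced, "XY")


class TestDetectableEffect:
    def test_inversion_identity_returns_design_effect(self, stub_fit_factory):
        """Evaluating at the (pre-ceiling) SSE returns exactly the 20%
        design effect size."""
        fit = stub_fit_factory()
        n_raw = sample_size_estimate(fit, DESIGN_CI, ceiling=False)
        pct = detectable_effect(fit, n_raw, DESIGN_CI)
        assert pct == pytest.approx(100 * DESIGN_CI.pct_change, rel=1e-12)

    def test_worked_example_returns_twenty_percent(self, stub_fit_factory):
        wk = 52.0
        fit = stub_fit_factory(
            slope=0.0005 * wk, var_b1=(0.001 * wk) ** 2, sigma=0.05
        )
        assert detectable_effect(fit, 2860, DESIGN_CI) == pytest.approx(
            20.0, abs=0.01
        )

    def test_sqrt_scaling_in_n(self, stub_fit_factory):
        fit = stub_fit_factory()
        e1 = detectable_effect(fit, 100, DESIGN_CI)
        e4 = detectable_effect(fit, 400, DESIGN_CI)
        assert e1 / e4 == pytest.approx(2.0, rel=1e-12)

    def test_zero_slope_rejected(self, stub_fit_factory):
        with pytest.raises(ValueError, match="zero"):
            detectable_effect(stub_fit_factory(slope=0.0), 100, DESIGN_CI)


class TestPowerSimulation:
    def test_power_at_design_n_close_to_nominal(self, stub_fit_factory):
        """Monte-Carlo power at n = SSE approximates the design's 80%."""
        fit = stub_fit_factory(slope=-0.03, var_b1=2.5e-5, sigma=0.04)
        power = simulate_trial_power(fit, DESIGN_CI, n_trials=4000, seed=2)
        assert power == pytest.approx(0.80, abs=0.03)

    def test_more_subjects_increase_power(self, stub_fit_factory):
        fit = stub_fit_factory(slope=-0.03, var_b1=2.5e-5, sigma=0.04)
        n = sample_size_estimate(fit, DESIGN_CI)
        low = simulate_trial_power(fit, DESIGN_CI, n_per_arm=n // 2,
                                   n_trials=2000, seed=3)
        high = simulate_trial_power(fit, DESIGN_CI, n_per_arm=2 * n,
                                    n_trials=2000, seed=3)
        assert low < 0.7 < high


class TestBootstrap:
    def test_constant_metric_gives_zero_width_interval(self, hv_series):
        ci = bootstrap_ci(hv_series, lambda fit: 42.0, n_boot=25, seed=0)
        assert (ci.point, ci.ci_low, ci.ci_high) == (42.0, 42.0, 42.0)
        assert ci.reliable

    def test_same_seed_reproduces_interval(self, hv_series):
        a = bootstrap_ci(hv_series, percentage_error, n_boot=40, seed=9)
        b = bootstrap_ci(hv_series, percentage_error, n_boot=40, seed=9)
        assert a == b
        assert a.ci_low <= a.point <= a.ci_high

    def test_delta_method_sse_interval_brackets_estimate(self, hv_series):
        fit = fit_lmm(hv_series)
        lo, hi = sse_confint(fit, DESIGN_CI)
        point = sample_size_estimate(fit, DESIGN_CI, ceiling=False)
        assert 0 < lo < point < hi

    def test_slope_variance_decomposition(self, stub_fit_factory):
        fit = stub_fit_factory(var_b1=1e-4, sigma=0.05)
        expected = 1e-4 + 0.05**2 / (1.5**2 / 2)
        assert slope_variance(fit, DESIGN_CI) == pytest.approx(expected)


class TestMetricReport:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="sse"):
            MetricReport("x", "CI", sse=0.0)
        with pytest.raises(ValueError, match="error_pct"):
            MetricReport("x", "CI", sse=10.0, error_pct=-1.0)
        with pytest.raises(ValueError, match="outside"):
            MetricReport("x", "CI", sse=10.0, sse_ci=(12.0, 20.0))

    def test_row_formatting_carries_cis(self):
        rep = MetricReport("ventricles_icv", "CI", sse=812.0,
                           sse_ci=(596.0, 1171.0), error_pct=7.86,
                           error_ci=(7.47, 8.27), t_ab=7.79, t_dx=2.02)
        row = rep.to_row()
        assert row["sse"] == "812 (596, 1171)"
        assert row["biomarker"] == "ventricles_icv"
        assert rep.to_dict()["t_ab"] == 7.79
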