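import numpy as np
import pytest
from scipy.stats import norm

from conftest import make_table
from metaroc.observer_sim import ExperimentDesign, ObserverParams, simulate_subject
from metaroc.sdt_model import (
    expected_asymmetry,
    expected_rcroc,
    fit_sdt,
    fit_sdt_from_table,
    h3_statistic,
    zroc_points,
    zroc_slope,
)


class TestFitSdt:
    def test_chance_performance(self):
        fit = fit_sdt(50, 50, 50, 50)
        assert fit.dprime == pytest.approx(0.0)
        assert fit.criterion_c == pytest.approx(0.0)
        assert fit.threshold_k == pytest.approx(0.0)
        assert not fit.correction_applied

    def test_symmetric_rates(self):
        fit = fit_sdt(69, 31, 31, 69)
        assert fit.dprime == pytest.approx(2 * norm.ppf(0.69), abs=1e-9)
        assert fit.dprime == pytest.approx(0.9917, abs=1e-3)
        assert fit.criterion_c == pytest.approx(0.0, abs=1e-9)

    def test_biased_rates(self):
        fit = fit_sdt(90, 10, 30, 70)
        assert fit.dprime == pytest.approx(1.8061, abs=1e-3)
        assert fit.criterion_c == pytest.approx(-0.3786, abs=1e-3)
        assert fit.threshold_k == pytest.approx(-norm.ppf(0.3), abs=1e-9)

    def test_loglinear_correction_on_zero_cell(self):
        fit = fit_sdt(80, 0, 20, 60)
        assert fit.correction_applied
        assert fit.hit_rate == pytest.approx(80.5 / 81)
        assert np.isfinite(fit.dprime)

    def test_absent_stimulus_class_rejected(self):
        with pytest.raises(ValueError):
            fit_sdt(0, 0, 10, 10)


class TestExpectedRcRoc:
    def test_unbiased_model_is_symmetric(self):
        # criterion at d'/2: both responses are statistically identical,
        # so identical incorrect-confidence quantiles give identical curves
        fit = fit_sdt(70, 30, 30, 70)
        inc = np.array([0.1, 0.3, 0.5, 0.7])
        auc_s1 = expected_rcroc(fit, inc, "S1").auc
        auc_s2 = expected_rcroc(fit, inc, "S2").auc
        assert auc_s1 == pytest.approx(auc_s2, abs=1e-12)

    def test_single_confidence_level_degenerates_to_chance(self):
        fit = fit_sdt(70, 30, 30, 70)
        curve = expected_rcroc(fit, np.array([0.5, 0.5, 0.5]), "S1")
        np.testing.assert_allclose(curve.points, [[0, 0], [1, 1]])
        assert curve.auc == 0.5

    def test_matches_monte_carlo_quantiles(self):
        # frozen 10^6-sample Monte Carlo of the d'=1, k=0.2 equal-variance
        # observer (confidence = distance from threshold), at incorrect
        # cumulative proportions ~{0.25, 0.5, 0.75}
        from metaroc.sdt_model import SdtFit

        fit = SdtFit(
            hit_rate=norm.sf(0.2 - 1.0),
            fa_rate=norm.sf(0.2),
            dprime=1.0,
            criterion_c=0.0,
            threshold_k=0.2,
            correction_applied=False,
        )
        # incorrect confidences whose at-or-above cumfracs are .25/.5/.75/1
        inc = np.array([0.8, 0.6, 0.4, 0.2])
        mc = {
            "S1": [0.50854, 0.73362, 0.88651],
            "S2": [0.46428, 0.69275, 0.86179],
        }
        for resp, q_mc in mc.items():
            curve = expected_rcroc(fit, inc, resp)
            np.testing.assert_allclose(curve.points[1:4, 0], [0.25, 0.5, 0.75])
            np.testing.assert_allclose(curve.points[1:4, 1], q_mc, atol=0.005)

    def test_curve_construction_uses_empirical_fprs(self):
        fit = fit_sdt(75, 25, 20, 80)
        inc = np.array([0.9, 0.6, 0.6, 0.3])
        curve = expected_rcroc(fit, inc, "S1")
        np.testing.assert_allclose(curve.points[:, 0], [0, 0.25, 0.75, 1.0])
        assert np.all(np.diff(curve.points[:, 1]) >= 0)


class TestH3Statistic:
    def test_invariant_to_monotone_confidence_transform(self):
        rng = np.random.default_rng(6)
        p = ObserverParams(metacog_noise_sd=0.0, lapse_rate=0.0)
        table = simulate_subject(
            p, ExperimentDesign(n_subjects=1, n_trials=480, n_blocks=6), rng
        )
        base = h3_statistic(table)
        warped = table.copy()
        warped["confidence"] = warped["confidence"] ** 3
        assert h3_statistic(warped) == pytest.approx(base, abs=1e-12)

    def test_self_consistency_of_matched_model(self):
        # data generated by the equal-variance model the null fits:
        # observed and expected asymmetry agree on average
        rng = np.random.default_rng(12)
        p = ObserverParams(
            criterion_shift=0.3, metacog_noise_sd=0.0, lapse_rate=0.0,
            comprehension_fail_prob=0.0,
        )
        vals = []
        for _ in range(60):
            table = simulate_subject(
                p, ExperimentDesign(n_trials=480, n_blocks=6, fixed_soa_ms=35.0), rng
            )
            vals.append(h3_statistic(table))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 2 * se + 0.005

    def test_expected_asymmetry_absorbs_bias(self):
        # the raw asymmetry of a biased equal-variance observer is nonzero,
        # but the SDT-matched expectation reproduces it
        rng = np.random.default_rng(23)
        p = ObserverParams(
            criterion_shift=0.4, metacog_noise_sd=0.0, lapse_rate=0.0
        )
        table = simulate_subject(
            p, ExperimentDesign(n_trials=4800, n_blocks=6, fixed_soa_ms=35.0), rng
        )
        from metaroc.metacog import subject_asymmetry

        observed = subject_asymmetry(table).delta_auc
        expected = expected_asymmetry(table)
        assert observed != 0
        assert observed == pytest.approx(expected, abs=0.05)


class TestZRoc:
    def test_exact_lines(self):
        fit = zroc_slope(np.array([[-1.0, -1.0], [0.0, 0.0], [1.0, 1.0]]))
        assert fit.slope == pytest.approx(1.0)
        assert fit.log_slope == pytest.approx(0.0)
        fit = zroc_slope(np.array([[-1.0, -0.8], [0.0, 0.0], [1.0, 0.8]]))
        assert fit.slope == pytest.approx(0.8)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            zroc_slope(np.array([[0.5, -1.0], [0.5, 0.0], [0.5, 1.0]]))

    def test_equal_variance_slope_is_unit(self):
        rng = np.random.default_rng(31)
        p = ObserverParams(metacog_noise_sd=0.0, lapse_rate=0.0)
        table = simulate_subject(
            p,
            ExperimentDesign(n_trials=50_000, n_blocks=10, fixed_soa_ms=40.0),
            rng,
        )
        fit = zroc_slope(zroc_points(table))
        assert fit.slope == pytest.approx(1.0, abs=0.03)

    def test_unequal_variance_slope_is_sigma_ratio(self, unequal_variance_subject):
        fit = zroc_slope(zroc_points(unequal_variance_subject))
        assert fit.slope == pytest.approx(1 / 1.25, abs=0.04)

    def test_degenerate_rates_dropped(self):
        table = make_table(
            [0.9, 0.8, 0.7, 0.5, 0.3, 0.2, 0.9, 0.1],
            [True, True, False, True, False, True, True, False],
            responses=["S1", "S1", "S1", "S2", "S2", "S2", "S1", "S2"],
        )
        pts = zroc_points(table)
        assert np.isfinite(pts).all()

    def test_mean_log_slope_null_across_subjects(self):
        # equal-variance cohort: mean log zROC slope within 2 SE of 0
        rng = np.random.default_rng(77)
        p = ObserverParams(metacog_noise_sd=0.0, lapse_rate=0.0)
        logs = []
        for _ in range(60):
            table = simulate_subject(
                p, ExperimentDesign(n_trials=960, n_blocks=6, fixed_soa_ms=40.0), rng
            )
            logs.append(zroc_slope(zroc_points(table)).log_slope)
        logs = np.array(logs)
        se = logs.std(ddof=1) / np.sqrt(len(logs))
        assert abs(logs.mean()) < 2 * se + 0.01
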