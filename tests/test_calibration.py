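import dataclasses
import warnings

import numpy as np
import pytest

from adcresponse import (
    ModelParams,
    SubjectSeries,
    analytic_trajectory,
    fit_treated_flank,
    fit_treated_ic,
    fit_untreated,
    infer_C0,
    pool_growth_rate,
    run_pipeline,
    weekly_schedule,
)
from adcresponse.calibration import (
    FitParam,
    StepFitResult,
    multistart_least_squares,
)
from adcresponse.cohort import CohortDesign, default_truth_distributions, simulate_cohort
from adcresponse.sensitivity import ParamDistribution

DAYS = np.arange(0.0, 85.0, 7.0)


def control_series(rho, C0, sid="c1", site="flank", days=DAYS, noise=None, rng=None):
    flux = C0 * np.exp(rho * days)
    if noise:
        flux = flux * 10.0 ** rng.normal(0.0, noise, size=days.size)
    return SubjectSeries(sid, site, "control", days, flux)


def treated_series(params, schedule, sid="t1", site="flank", days=DAYS):
    traj = analytic_trajectory(params, schedule, days)
    return SubjectSeries(sid, site, "treated", days, traj.C, schedule.first_dose_day)


class TestUntreatedFit:
    def test_exact_recovery_from_noiseless_growth(self):
        r = fit_untreated(control_series(0.3, 1e4))
        assert r.estimates["rho"] == pytest.approx(0.3, rel=1e-6)
        assert r.estimates["C0"] == pytest.approx(1e4, rel=1e-6)
        assert r.converged and r.residual_norm < 1e-12

    def test_flat_series_pins_growth_rate_at_lower_bound(self):
        r = fit_untreated(control_series(0.0, 5e3))
        assert r.estimates["rho"] == pytest.approx(0.0, abs=1e-6)

    def test_mean_growth_rate_recovered_from_noisy_cohort(self):
        # Monte-Carlo recovery: 20 subjects, 8 weekly scans, lognormal noise
        rng = np.random.default_rng(314)
        days = np.arange(0.0, 56.0, 7.0)
        rhos = [
            fit_untreated(
                control_series(0.3, 1e4, sid=f"c{i}", days=days, noise=0.2, rng=rng)
            ).estimates["rho"]
            for i in range(20)
        ]
        assert np.mean(rhos) == pytest.approx(0.3, abs=0.02)

    def test_requires_at_least_three_points(self):
        with pytest.raises(ValueError):
            fit_untreated(
                SubjectSeries("c", "flank", "control", [0.0, 7.0], [1e4, 2e4])
            )

    def test_rejects_treated_series(self, schedule):
        s = treated_series(ModelParams(rho=0.3, mu_H=5, z=0.3, q=1e-3), schedule)
        with pytest.raises(ValueError):
            fit_untreated(s)

    def test_raw_and_log_scales_agree_on_noiseless_data(self):
        s = control_series(0.25, 3e3)
        r_log = fit_untreated(s, scale="log10")
        r_raw = fit_untreated(s, scale="raw")
        assert r_log.estimates["rho"] == pytest.approx(r_raw.estimates["rho"], rel=1e-5)
        assert r_log.estimates["C0"] == pytest.approx(r_raw.estimates["C0"], rel=1e-4)


class TestPooling:
    def test_two_subject_mean(self):
        fits = [fit_untreated(control_series(r, 1e4, sid=s)) for r, s in ((0.2, "a"), (0.4, "b"))]
        assert pool_growth_rate(fits, "flank") == pytest.approx(0.3, rel=1e-5)

    def test_single_subject_identity(self):
        fit = fit_untreated(control_series(0.27, 1e4))
        assert pool_growth_rate([fit], "flank") == pytest.approx(0.27, rel=1e-6)

    def test_pooled_value_stays_inside_generating_range(self):
        rng = np.random.default_rng(9)
        fits = [
            fit_untreated(control_series(rng.uniform(0.2, 0.5), 1e4, sid=f"c{i}"))
            for i in range(8)
        ]
        assert 0.2 <= pool_growth_rate(fits, "flank") <= 0.5

    def test_empty_or_mismatched_collections_rejected(self):
        with pytest.raises(ValueError):
            pool_growth_rate([], "flank")
        fit = fit_untreated(control_series(0.3, 1e4, site="intracranial"))
        with pytest.raises(ValueError):
            pool_growth_rate([fit], "flank")


class TestInferC0:
    def test_day_zero_anchor_is_first_flux(self, schedule):
        s = treated_series(ModelParams(rho=0.3, mu_H=5, z=0.3, q=1e-3, C0=1e4), schedule)
        assert infer_C0(s, 0.3) == pytest.approx(1e4, rel=1e-12)

    def test_one_doubling_time_back_projection(self):
        days = np.arange(7.0, 85.0, 7.0)
        s = SubjectSeries("t", "flank", "treated", days, np.full(days.size, 2e4), 7.0)
        assert infer_C0(s, np.log(2) / 7.0) == pytest.approx(1e4, rel=1e-12)

    def test_round_trip_through_forward_model(self, no_dose):
        p = ModelParams(rho=0.31, mu_H=5, z=0.3, q=1e-3, C0=7.3e3)
        traj = analytic_trajectory(p, no_dose, DAYS)
        s = SubjectSeries("t", "flank", "treated", DAYS, traj.C, 7.0)
        c0 = infer_C0(s, p.rho)
        assert c0 * np.exp(p.rho * DAYS[0]) == pytest.approx(s.flux[0], rel=1e-12)

    def test_out_of_bound_inference_clipped_with_warning(self):
        s = SubjectSeries("t", "flank", "treated", [0.0, 7.0, 14.0], [10.0, 20.0, 40.0], 7.0)
        with pytest.warns(UserWarning, match="clipping"):
            assert infer_C0(s, 0.1) == 1e2

    def test_no_pretreatment_observation_rejected(self):
        days = np.array([14.0, 21.0, 28.0])
        s = SubjectSeries("t", "flank", "treated", days, [1e4, 2e4, 4e4], 7.0)
        with pytest.raises(ValueError, match="pre-treatment"):
            infer_C0(s, 0.3)


class TestTreatedFlankFit:
    def test_exact_recovery_from_noiseless_data(self, schedule):
        p = ModelParams(rho=0.3, mu_H=5.0, z=0.3, q=1e-3, gamma=1.0, C0=1e4)
        r = fit_treated_flank(treated_series(p, schedule), 0.3, schedule)
        assert r.estimates["mu_H"] == pytest.approx(5.0, rel=1e-3)
        assert r.estimates["z"] == pytest.approx(0.3, rel=1e-3)
        assert r.estimates["q"] == pytest.approx(1e-3, rel=1e-3)

    def test_vanishing_resistant_clone_fits_single_population_kill(self, schedule):
        p = ModelParams(rho=0.3, mu_H=4.0, z=0.5, q=1e-10, gamma=1.0, C0=1e4)
        r = fit_treated_flank(treated_series(p, schedule), 0.3, schedule)
        assert r.residual_norm < 1e-10

    def test_estimates_respect_bounds_on_noisy_fits(self, schedule):
        rng = np.random.default_rng(77)
        dists = default_truth_distributions()
        n_ok = 0
        for i in range(100):
            p = ModelParams(
                rho=0.3,
                mu_H=rng.uniform(1.0, 10.0),
                z=rng.uniform(0.0, 1.0),
                q=10.0 ** rng.uniform(-8, -2),
                gamma=1.0,
                C0=10.0 ** rng.uniform(3, 5),
            )
            traj = analytic_trajectory(p, schedule, DAYS)
            flux = traj.C * 10.0 ** rng.normal(0, 0.2, DAYS.size)
            s = SubjectSeries(f"t{i}", "flank", "treated", DAYS, flux, 7.0)
            r = fit_treated_flank(s, 0.3, schedule)
            assert 1.0 <= r.estimates["mu_H"] <= 10.0
            assert 0.0 <= r.estimates["z"] <= 1.0
            assert 1e-10 <= r.estimates["q"] <= 1e-2
            n_ok += r.converged
        assert n_ok == 100

    def test_rejects_wrong_site(self, schedule):
        p = ModelParams(rho=0.3, mu_H=5, z=0.3, q=1e-3)
        s = treated_series(p, schedule, site="intracranial")
        with pytest.raises(ValueError):
            fit_treated_flank(s, 0.3, schedule)


class TestTreatedIntracranialFit:
    def test_exact_recovery_given_matching_kill_rate(self, schedule):
        p = ModelParams(rho=0.4, mu_H=5.0, z=0.3, q=1e-3, gamma=0.4, C0=1e4)
        s = treated_series(p, schedule, site="intracranial")
        r = fit_treated_ic(s, 0.4, 5.0, schedule)
        assert r.estimates["gamma"] == pytest.approx(0.4, rel=1e-3)
        assert r.estimates["z"] == pytest.approx(0.3, rel=1e-3)
        assert r.estimates["q"] == pytest.approx(1e-3, rel=1e-3)

    def test_full_exposure_matches_flank_fit(self, schedule):
        p = ModelParams(rho=0.3, mu_H=6.0, z=0.4, q=1e-4, gamma=1.0, C0=1e4)
        s_ic = treated_series(p, schedule, site="intracranial")
        s_fl = treated_series(p, schedule, site="flank")
        r_ic = fit_treated_ic(s_ic, 0.3, 6.0, schedule)
        r_fl = fit_treated_flank(s_fl, 0.3, schedule)
        assert r_ic.estimates["gamma"] == pytest.approx(1.0, abs=1e-4)
        assert r_ic.estimates["z"] == pytest.approx(r_fl.estimates["z"], rel=1e-3)
        assert r_ic.estimates["q"] == pytest.approx(r_fl.estimates["q"], rel=1e-2)

    def test_doubled_passed_kill_rate_halves_fitted_exposure(self, schedule):
        # only the product gamma*mu_H is identifiable within one site
        p = ModelParams(rho=0.4, mu_H=4.0, z=0.3, q=1e-3, gamma=0.5, C0=1e4)
        s = treated_series(p, schedule, site="intracranial")
        g1 = fit_treated_ic(s, 0.4, 4.0, schedule).estimates["gamma"]
        g2 = fit_treated_ic(s, 0.4, 8.0, schedule).estimates["gamma"]
        assert g2 == pytest.approx(g1 / 2.0, rel=1e-3)


class TestMultistart:
    def test_unique_optimum_gives_negligible_spread(self):
        r = fit_untreated(control_series(0.3, 1e4))
        assert r.multistart_spread < 1e-6

    def test_spread_always_reported(self, schedule):
        p = ModelParams(rho=0.3, mu_H=5.0, z=0.3, q=1e-3)
        r = fit_treated_flank(treated_series(p, schedule), 0.3, schedule)
        assert np.isfinite(r.multistart_spread) and r.multistart_spread >= 0.0

    def test_best_start_attains_minimal_residual(self):
        # min-selection: the returned SSR is <= every single-start SSR
        rng = np.random.default_rng(3)
        t = np.linspace(0, 10, 12)
        y = 2.0 * np.exp(0.3 * t) + rng.normal(0, 0.5, t.size)
        params = [FitParam("a", 0.1, 10.0), FitParam("b", 0.0, 1.0)]

        def residual(v):
            return v["a"] * np.exp(v["b"] * t) - y

        _, best_ssr, _, _ = multistart_least_squares(residual, params)
        for frac in (0.25, 0.5, 0.75):
            _, ssr, _, _ = multistart_least_squares(residual, params, (frac,))
            assert best_ssr <= ssr + 1e-12

    def test_estimates_outside_bounds_rejected_in_results(self):
        with pytest.raises(ValueError):
            StepFitResult(
                step_label="untreated",
                estimates={"rho": 2.0},
                bounds_used={"rho": (0.0, 1.0)},
                residual_norm=0.0,
                converged=True,
                multistart_spread=0.0,
            )


def shared_truth():
    """Truth distributions matching the pipeline's pooling assumptions."""
    td = default_truth_distributions()
    td["rho_flank"] = ParamDistribution("rho_flank", "uniform", 0.3, 0.3)
    td["rho_intracranial"] = ParamDistribution("rho_intracranial", "uniform", 0.4, 0.4)
    td["mu_H"] = ParamDistribution("mu_H", "uniform", 5.0, 5.0)
    return td


class TestPipeline:
    def test_full_cohort_end_to_end(self, schedule):
        design = CohortDesign(noise_sigma_log=0.1, seed=21)
        series, truth = simulate_cohort(design, schedule=schedule)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calib = run_pipeline(series, schedule)
        assert len(calib.per_subject) == 18  # (4 control + 5 treated) x 2 sites
        assert 0.2 <= calib.rho_flank_mean <= 0.5
        assert 0.2 <= calib.rho_ic_mean <= 0.5
        assert 1.0 <= calib.mu_H_mean <= 10.0
        assert "pooled" in calib.summary()

    def test_controls_only_runs_step_one_only(self, schedule):
        design = CohortDesign(n_treated_per_site=0, noise_sigma_log=0.0, seed=4)
        series, _ = simulate_cohort(design, schedule=schedule)
        with pytest.warns(UserWarning):
            calib = run_pipeline(series, schedule)
        assert calib.mu_H_mean is None
        assert all(r.step_label == "untreated" for r in calib.per_subject)

    def test_treated_without_controls_is_an_error(self, schedule):
        design = CohortDesign(n_control_per_site=0, noise_sigma_log=0.0, seed=4)
        series, _ = simulate_cohort(design, schedule=schedule)
        with pytest.raises(ValueError, match="pooled growth rate"):
            run_pipeline(series, schedule)

    def test_subject_order_does_not_change_pooled_means(self, schedule):
        design = CohortDesign(noise_sigma_log=0.15, seed=8)
        series, _ = simulate_cohort(design, schedule=schedule)
        calib1 = run_pipeline(series, schedule)
        rng = np.random.default_rng(0)
        shuffled = list(series)
        rng.shuffle(shuffled)
        calib2 = run_pipeline(shuffled, schedule)
        assert calib1.rho_flank_mean == calib2.rho_flank_mean
        assert calib1.rho_ic_mean == calib2.rho_ic_mean
        assert calib1.mu_H_mean == calib2.mu_H_mean

    def test_fixed_seed_reproduces_calibration_bit_identically(self, schedule):
        frames = []
        for _ in range(2):
            design = CohortDesign(noise_sigma_log=0.2, seed=33)
            series, _ = simulate_cohort(design, schedule=schedule)
            frames.append(run_pipeline(series, schedule).to_frame())
        assert frames[0].equals(frames[1])

    def test_no_step_fits_more_than_three_parameters(self, schedule):
        design = CohortDesign(noise_sigma_log=0.1, seed=2)
        series, _ = simulate_cohort(design, schedule=schedule)
        calib = run_pipeline(series, schedule)
        assert max(len(r.estimates) for r in calib.per_subject) <= 3
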