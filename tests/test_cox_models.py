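import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq, minimize_scalar

from ivsurvsim import (
    ScenarioSpec,
    lookup_coefficients,
    simulate_observational_cohort,
    fit_treatment_model,
)
from ivsurvsim.cox_models import (
    CoxFitError,
    StructuralCoxNoSolutionError,
    fit_cox,
    fit_cox_binary_aggregated,
    fit_cox_two_stage,
    fit_structural_cox,
    predict_survival_cox,
)
from ivsurvsim.first_stage import FirstStageFit

from conftest import make_cohort


def breslow_loglik(theta, times, events, x):
    """Printed Breslow partial likelihood, assembled by explicit loops."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = times >= times[i]
        ll += theta * x[i] - math.log(np.sum(np.exp(theta * x[risk])))
    return ll


class TestFitCox:
    def test_five_subject_brute_force_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.ones(5, int)
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
        fit = fit_cox(times, events, x[:, None], names=("x",))
        res = minimize_scalar(
            lambda th: -breslow_loglik(th, times, events, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-12},
        )
        assert fit.theta[0] == pytest.approx(res.x, abs=1e-8)

    def test_identical_groups_give_zero(self):
        times = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        events = np.ones(6, int)
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        fit = fit_cox(times, events, x[:, None], names=("x",))
        assert fit.theta[0] == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(12)
        n = 400
        W = np.column_stack([rng.integers(0, 2, n).astype(float), rng.standard_normal(n)])
        latent = rng.exponential(1.0, n) / np.exp(0.5 * W[:, 0] - 0.3 * W[:, 1])
        times = np.minimum(latent, 2.0)
        events = (latent <= 2.0).astype(int)
        fit = fit_cox(times, events, W, names=("x", "cm"))
        df = pd.DataFrame({"t": times, "e": events, "x": W[:, 0], "cm": W[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(fit.theta, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_breslow_baseline_against_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(13)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        latent = rng.exponential(1.5, n) / np.exp(0.4 * x)
        times = np.minimum(latent, 2.5)
        events = (latent <= 2.5).astype(int)
        fit = fit_cox(times, events, x[:, None], names=("x",))
        df = pd.DataFrame({"t": times, "e": events, "x": x})
        cph = lifelines.CoxPHFitter(baseline_estimation_method="breslow").fit(
            df, duration_col="t", event_col="e"
        )
        base = cph.baseline_cumulative_hazard_
        grid = base.index.to_numpy(float)
        vals = base.iloc[:, 0].to_numpy(float)
        # lifelines centres its baseline at the covariate mean
        centring = math.exp(fit.theta[0] * x.mean())
        for t in (0.5, 1.0, 2.0):
            expected = float(vals[np.searchsorted(grid, t, side="right") - 1])
            assert fit.cumulative_baseline(t) * centring == pytest.approx(expected, rel=1e-4)

    def test_parameter_recovery_randomized(self):
        spec = ScenarioSpec("multiplicative", "exponential", "low", "large", "moderate", "weak")
        coeffs = replace(lookup_coefficients(spec), beta_cm=0.0, beta_cu=0.0)
        rng = np.random.default_rng(3)
        n = 50_000
        x = (rng.random(n) < 0.5).astype(float)
        u = rng.random(n) * (1 - 2e-9) + 1e-9
        latent = -np.log(u) / (coeffs.scale * np.exp(coeffs.beta_x * x))
        times = np.minimum(latent, 5.0)
        events = (latent <= 5.0).astype(int)
        fit = fit_cox(times, events, x[:, None], names=("x",))
        assert abs(fit.theta[0] - coeffs.beta_x) < 3 * fit.se[0]

    def test_weighted_fit_equals_expanded_data(self):
        rng = np.random.default_rng(4)
        n = 200
        times = rng.exponential(1.0, n) + 0.01
        events = (rng.random(n) < 0.8).astype(int)
        x = rng.integers(0, 2, n).astype(float)
        w = rng.integers(1, 4, n)
        expanded = np.repeat(np.arange(n), w)
        fit_w = fit_cox(times, events, x[:, None], weights=w.astype(float))
        fit_e = fit_cox(times[expanded], events[expanded], x[expanded, None])
        assert fit_w.theta[0] == pytest.approx(fit_e.theta[0], abs=1e-8)

    def test_constant_covariate_rejected(self):
        with pytest.raises(CoxFitError):
            fit_cox([1.0, 2.0, 3.0], [1, 1, 1], np.ones((3, 1)))

    def test_no_events_rejected(self):
        with pytest.raises(CoxFitError):
            fit_cox([1.0, 2.0], [0, 0], np.array([[0.0], [1.0]]))

    def test_separation_raises(self):
        # perfectly ordered: all treated events before any control
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.ones(6, int)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.raises(CoxFitError):
            fit_cox(times, events, x[:, None])


class TestAggregatedBinaryCox:
    @pytest.mark.parametrize("seed", range(3))
    def test_equals_generic_fitter(self, seed):
        rng = np.random.default_rng(seed)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        latent = rng.exponential(2.0, n) / np.exp(-0.4 * x)
        times = np.minimum(latent, 4.0)
        events = (latent <= 4.0).astype(int)
        generic = fit_cox(times, events, x[:, None], names=("x",))
        fast = fit_cox_binary_aggregated(times, events, x)
        assert fast == pytest.approx(generic.theta[0], abs=1e-8)


class TestCoxTwoStage:
    def test_constant_predictions_rejected(self):
        cohort = make_cohort(
            z=[0, 1] * 4, cm=np.zeros(8), cu=np.zeros(8), x=[0, 1] * 4,
            time=np.arange(1, 9, dtype=float), event=np.ones(8, int),
        )
        fs = FirstStageFit(
            eta=np.zeros(3), fitted=np.full(8, 0.5), residuals=cohort.x - 0.5,
            converged=True, n_iter=1,
        )
        with pytest.raises(CoxFitError):
            fit_cox_two_stage(cohort, fs)

    def test_benign_limit_recovery(self):
        spec = ScenarioSpec("multiplicative", "exponential", "low", "small", "strong", "weak")
        coeffs = replace(lookup_coefficients(spec), alpha_cu=0.0, beta_cu=0.0)
        cohort = simulate_observational_cohort(spec, coeffs, 50_000, 1)
        fit = fit_cox_two_stage(cohort, fit_treatment_model(cohort))
        assert np.exp(fit.theta[0]) == pytest.approx(np.exp(coeffs.beta_x), abs=3 * fit.se[0])

    def test_deterministic_given_cohort(self):
        spec = ScenarioSpec("multiplicative", "exponential", "low", "large", "moderate", "strong")
        coeffs = lookup_coefficients(spec)
        cohort = simulate_observational_cohort(spec, coeffs, 5000, 9)
        fs = fit_treatment_model(cohort)
        a = fit_cox_two_stage(cohort, fs)
        b = fit_cox_two_stage(cohort, fs)
        assert a.theta[0] == b.theta[0]


class TestStructuralCox:
    def _fixture_cohort(self):
        return make_cohort(
            z=[0, 0, 1, 1], cm=np.zeros(4), cu=np.zeros(4), x=[0, 1, 0, 1],
            time=np.ones(4), event=np.ones(4, int),
        )

    def test_four_subject_closed_form_fixture(self):
        # hand-solved linearised moment: A=0.15, B=-0.05, exp(-theta)=3
        surv = np.array([0.6, 0.9, 0.9, 0.8])
        fit = fit_structural_cox(
            self._fixture_cohort(), t_eval=1.0,
            survival_override=surv, moment="linear",
        )
        assert fit.theta == pytest.approx(-math.log(3), abs=1e-12)

    def test_linear_closed_form_equals_generic_root_finder(self):
        rng = np.random.default_rng(2)
        n = 50
        z = (rng.random(n) < 0.5).astype(float)
        x = (rng.random(n) < 0.5).astype(float)
        surv = rng.uniform(0.2, 0.95, n)
        cohort = make_cohort(
            z=z, cm=np.zeros(n), cu=np.zeros(n), x=x,
            time=np.ones(n), event=np.ones(n, int),
        )
        fit = fit_structural_cox(cohort, 1.0, survival_override=surv, moment="linear")
        g = z - z.mean()

        def eq(theta):
            return float(np.sum(g * surv * np.exp(-theta * x)))

        oracle = brentq(eq, -10, 10, xtol=1e-14)
        assert fit.theta == pytest.approx(oracle, abs=1e-10)

    def test_power_moment_equals_scipy_root(self):
        rng = np.random.default_rng(7)
        n = 200
        z = (rng.random(n) < 0.5).astype(float)
        x = (rng.random(n) < 0.4 + 0.3 * z).astype(float)
        surv = rng.uniform(0.3, 0.95, n)
        cohort = make_cohort(
            z=z, cm=np.zeros(n), cu=np.zeros(n), x=x,
            time=np.ones(n), event=np.ones(n, int),
        )
        fit = fit_structural_cox(cohort, 1.0, survival_override=surv)
        g = z - z.mean()

        def eq(theta):
            return float(np.sum(g * surv ** np.exp(-theta * x)))

        oracle = brentq(eq, -10, 10, xtol=1e-12)
        assert fit.theta == pytest.approx(oracle, abs=1e-9)

    def test_no_solution_reported(self):
        # untreated and treated sums share a sign, so -A/B <= 0
        cohort = make_cohort(
            z=[0, 1, 0, 1], cm=np.zeros(4), cu=np.zeros(4), x=[0, 0, 1, 1],
            time=np.ones(4), event=np.ones(4, int),
        )
        surv = np.array([0.9, 0.6, 0.9, 0.6])
        with pytest.raises(StructuralCoxNoSolutionError):
            fit_structural_cox(cohort, 1.0, survival_override=surv, moment="linear")

    def test_null_effect_recovery(self):
        spec = ScenarioSpec("multiplicative", "exponential", "low", "large", "strong", "strong")
        coeffs = replace(lookup_coefficients(spec), beta_x=0.0)
        cohort = simulate_observational_cohort(spec, coeffs, 50_000, 21)
        fit = fit_structural_cox(cohort)
        assert abs(fit.theta) < 0.06

    def test_recovery_against_ett_oracle(self):
        import warnings

        from ivsurvsim import true_ett

        spec = ScenarioSpec("multiplicative", "exponential", "low", "large", "moderate", "strong")
        coeffs = lookup_coefficients(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            truth = true_ett(spec, coeffs, n_mc=300_000, seed=4, years=(5,))
        ett = truth.hr_ett[0]
        cohort = simulate_observational_cohort(spec, coeffs, 200_000, 8)
        fit = fit_structural_cox(cohort, t_eval=5.0)
        # effect modification by Z is not guaranteed in the multiplicative
        # DGM, so only closeness (not exact consistency) is expected
        assert fit.hazard_ratio == pytest.approx(ett, abs=0.05)

    def test_t_eval_variation_surfaces_different_estimates(self):
        spec = ScenarioSpec("multiplicative", "weibull_increasing", "low", "large", "strong", "strong")
        coeffs = lookup_coefficients(spec)
        cohort = simulate_observational_cohort(spec, coeffs, 30_000, 2)
        fits = [fit_structural_cox(cohort, t_eval=float(t)).theta for t in (2.0, 5.0)]
        assert fits[0] != fits[1]

    def test_constant_instrument_rejected(self):
        cohort = make_cohort(
            z=np.ones(6), cm=np.zeros(6), cu=np.zeros(6), x=[0, 1] * 3,
            time=np.arange(1, 7, dtype=float), event=np.ones(6, int),
        )
        with pytest.raises(CoxFitError):
            fit_structural_cox(cohort, 5.0)

    def test_bootstrap_se_available(self):
        spec = ScenarioSpec("multiplicative", "exponential", "low", "large", "strong", "moderate")
        coeffs = lookup_coefficients(spec)
        cohort = simulate_observational_cohort(spec, coeffs, 2000, 5)
        fit = fit_structural_cox(cohort, n_bootstrap=25, seed=1)
        assert fit.se is not None and fit.se > 0


class TestPredictSurvivalCox:
    def test_matches_kaplan_meier_on_randomized_effect_free_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(10)
        n = 40_000
        x = (rng.random(n) < 0.5).astype(float)
        latent = rng.exponential(4.0, n)
        times = np.minimum(latent, 5.0)
        events = (latent <= 5.0).astype(int)
        fit = fit_cox(times, events, x[:, None], names=("x",))
        km = lifelines.KaplanMeierFitter().fit(times, events)
        for t in (1.0, 3.0, 4.5):
            km_val = float(km.survival_function_at_times(t).iloc[0])
            for arm in (0, 1):
                assert predict_survival_cox(fit, arm, t) == pytest.approx(km_val, abs=0.02)

    def test_monotone_non_increasing(self):
        spec = ScenarioSpec("multiplicative", "exponential", "low", "large", "moderate", "strong")
        coeffs = lookup_coefficients(spec)
        cohort = simulate_observational_cohort(spec, coeffs, 4000, 1)
        fit = fit_cox(
            cohort.time, cohort.event,
            np.column_stack([cohort.x, cohort.cm]), names=("x", "cm"),
        )
        grid = np.linspace(0.2, 5.0, 25)
        vals = [predict_survival_cox(fit, 1, t) for t in grid]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
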