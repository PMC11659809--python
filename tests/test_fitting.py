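"""Summed-R² objective, Nelder-Mead recovery, curvature SEs, envelopes."""

import numpy as np
import pytest

import lacshift as ls
from lacshift.fitting import (FitResult, curvature_standard_errors,
                              fit_nelder_mead, objective,
                              objective_components, prediction_envelope,
                              r_squared, standard_errors)


class TestRSquared:
    def test_perfect_fit_is_one(self):
        obs = np.array([1.0, 2.0, 5.0])
        assert r_squared(obs, obs) == 1.0

    def test_mean_predictor_is_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_worked_example(self):
        assert r_squared([1, 2, 3], [1.1, 1.9, 3.2]) == pytest.approx(0.97)

    def test_can_be_negative(self):
        assert r_squared([1, 2, 3], [3, 2, 1]) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestObjective:
    def test_self_fit_equals_component_count(self, params_A, design_A,
                                             noisefree_A):
        meas, _ = noisefree_A
        assert objective(params_A, meas, design_A) == \
            pytest.approx(len(meas), abs=1e-6)

    def test_missing_component_drops_at_most_one(self, params_A, design_A,
                                                 noisefree_A, fast_solver):
        meas, _ = noisefree_A
        full = objective(params_A, meas, design_A, solver=fast_solver)
        reduced = dict(meas)
        del reduced["GLN"]
        partial = objective(params_A, reduced, design_A, solver=fast_solver)
        assert full - 1.0 <= partial <= full

    def test_perturbing_qp_decreases_objective(self, params_A, design_A,
                                               noisefree_A, fast_solver):
        meas, _ = noisefree_A
        base = objective(params_A, meas, design_A, solver=fast_solver)
        worse = objective(params_A.with_values(q_p=1.5 * params_A.q_p),
                          meas, design_A, solver=fast_solver)
        assert worse < base

    def test_failed_simulation_maps_to_penalty(self, params_A, design_C,
                                               noisefree_A):
        meas, _ = noisefree_A
        # reactor-type mismatch aborts the simulation inside the objective
        assert objective(params_A, meas, design_C) == -1.0e6


class TestNelderMead:
    FREE3 = ("mu_max1", "K_glc", "q_p")

    def test_zero_budget_returns_start(self, params_A, design_A, noisefree_A,
                                       fast_solver):
        meas, _ = noisefree_A
        res = fit_nelder_mead(params_A, self.FREE3, meas, design_A,
                              solver=fast_solver, maxiter=0)
        assert res.params.to_dict() == params_A.to_dict()
        assert res.n_evaluations == 0

    def test_noise_free_recovery_within_five_percent(self, params_A, design_B,
                                                     noisefree_B, fast_solver):
        meas, _ = noisefree_B
        start = params_A.with_values(
            mu_max1=1.2 * params_A.mu_max1, K_glc=0.8 * params_A.K_glc,
            q_p=1.2 * params_A.q_p)
        res = fit_nelder_mead(start, self.FREE3, meas, design_B,
                              solver=fast_solver, maxiter=400)
        for name in self.FREE3:
            est, true = res.params.get(name), params_A.get(name)
            assert abs(est - true) / true < 0.05, name
        assert res.objective > len(meas) - 0.05

    def test_deterministic_given_start_and_options(self, params_A, design_B,
                                                   noisefree_B, fast_solver):
        meas, _ = noisefree_B
        start = params_A.with_values(q_p=1.1 * params_A.q_p)
        a = fit_nelder_mead(start, ("q_p",), meas, design_B,
                            solver=fast_solver, maxiter=50)
        b = fit_nelder_mead(start, ("q_p",), meas, design_B,
                            solver=fast_solver, maxiter=50)
        assert a.params.q_p == b.params.q_p
        assert a.objective == b.objective

    def test_empty_free_list_rejected(self, params_A, design_A, noisefree_A):
        with pytest.raises(ValueError):
            fit_nelder_mead(params_A, (), noisefree_A[0], design_A)


class TestStandardErrors:
    def test_quadratic_curvature_analytic(self):
        # negated objective a*(x-x0)^2 has SE = 1/sqrt(2a)
        for a in (0.5, 2.0, 50.0):
            ses, flags = curvature_standard_errors(
                lambda x, a=a: a * (x[0] - 1.0) ** 2, np.array([1.0]))
            assert ses[0] == pytest.approx(1.0 / np.sqrt(2 * a), rel=1e-4)
            assert flags == [None]

    def test_non_positive_curvature_flagged(self):
        ses, flags = curvature_standard_errors(
            lambda x: -(x[0] - 1.0) ** 2, np.array([1.0]))
        assert np.isnan(ses[0])
        assert flags[0] == "hessian_not_positive_definite"

    def test_fixed_parameters_get_no_entry(self, params_A, design_B,
                                           noisefree_B, fast_solver):
        meas, _ = noisefree_B
        res = fit_nelder_mead(params_A, ("q_p",), meas, design_B,
                              solver=fast_solver, maxiter=100)
        ses = standard_errors(res, meas, design_B, solver=fast_solver)
        assert set(ses) == {"q_p"}
        assert ses["q_p"] > 0

    def test_denser_data_does_not_inflate_se(self, params_A, design_B,
                                             fast_solver):
        """More samples mean more curvature in the summed-R² surface per
        parameter, never less."""
        ses = {}
        for label, dt in (("daily", 24.0), ("twice_daily", 12.0)):
            times = np.append(np.arange(0.0, design_B.duration, dt),
                              design_B.duration)
            meas, _ = ls.generate_experiment(
                params_A, design_B, sampling_times=times,
                noise=ls.NoiseModel(cv=0.0, seed=0))
            res = FitResult(params=params_A, free=("q_p", "mu_max1"),
                            start={}, objective=float(len(meas)), r2={},
                            n_iterations=0, n_evaluations=0, converged=True,
                            message="at truth")
            ses[label] = standard_errors(res, meas, design_B,
                                         solver=fast_solver)
        assert ses["twice_daily"]["q_p"] <= ses["daily"]["q_p"] * 1.05

    def test_se_shrinks_with_noise(self, params_A, design_B, fast_solver):
        """Curvature SEs at the generating optimum shrink as assay CV drops."""
        out = {}
        for cv in (0.10, 0.02):
            meas, _ = ls.generate_experiment(
                params_A, design_B, noise=ls.NoiseModel(cv=cv, seed=3))
            res = fit_nelder_mead(params_A, ("q_p", "mu_max1"), meas,
                                  design_B, solver=fast_solver, maxiter=200)
            out[cv] = standard_errors(res, meas, design_B, solver=fast_solver)
        assert out[0.02]["q_p"] < out[0.10]["q_p"]


class TestEnvelope:
    def _result(self, params, free, ses):
        return FitResult(params=params, free=tuple(free), start={},
                         objective=float("nan"), r2={}, n_iterations=0,
                         n_evaluations=0, converged=True, message="fixture",
                         standard_errors=dict(ses))

    def test_zero_se_collapses_to_point(self, params_A, design_A):
        res = self._result(params_A, ("mu_max1", "q_p"),
                           {"mu_max1": 0.0, "q_p": 0.0})
        env = prediction_envelope(res, design_A, n_samples=20, seed=5)
        for comp in env.point:
            assert np.array_equal(env.lower[comp], env.upper[comp])

    def test_band_brackets_point_trajectory(self, params_A, params_A_se,
                                            design_A):
        free = ("mu_max1", "K_glc", "q_p")
        res = self._result(params_A, free, {n: params_A_se[n] for n in free})
        env = prediction_envelope(res, design_A, n_samples=50, seed=5)
        for comp in env.point:
            assert np.all(env.lower[comp] <= env.point[comp] + 1e-12)
            assert np.all(env.point[comp] <= env.upper[comp] + 1e-12)

    def test_reproducible_by_seed(self, params_A, params_A_se, design_A):
        free = ("mu_max1",)
        res = self._result(params_A, free, {"mu_max1": params_A_se["mu_max1"]})
        a = prediction_envelope(res, design_A, n_samples=20, seed=11)
        b = prediction_envelope(res, design_A, n_samples=20, seed=11)
        assert all(np.array_equal(a.upper[c], b.upper[c]) for c in a.upper)

    def test_missing_ses_rejected(self, params_A, design_A):
        res = self._result(params_A, ("q_p",), {})
        res.standard_errors = None
        with pytest.raises(ValueError):
            prediction_envelope(res, design_A, n_samples=5, seed=0)
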