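"""Tests of the nested estimation machinery.

Independent oracles: dense grid search over the feasible cone for the
constrained quadratic programs, direct matrix algebra for the GCV score,
and exhaustive enumeration for the delay grid.
"""

from dataclasses import replace

import numpy as np
import pytest

from pbpm import (FitConfig, IndividualParams, PopulationParams, build_basis,
                  default_delta_grid, evaluate_aif, fit_delta, fit_new_patient,
                  fit_pi, fit_theta, gcv_select_lambda, population_prior,
                  regularized_fit)
from pbpm.fit import gcv_score, inverse_logit_theta, logit_theta


from conftest import make_curve


# ---------------------------------------------------------------------------
# fit_pi: constrained linear step
# ---------------------------------------------------------------------------

class TestFitPi:
    def test_exact_interpolation(self, fdg_pop):
        t = np.linspace(0.25, 30, 12)
        pi_star = np.array([4.0, 1.5, 0.3])
        z = evaluate_aif(t, fdg_pop, IndividualParams(pi=tuple(pi_star)), 1.0)
        curve = make_curve(t, z)
        basis = build_basis(curve, fdg_pop, 0.0)
        assert fit_pi(curve, basis) == pytest.approx(pi_star, abs=1e-8)

    def test_single_component_closed_form(self):
        pop = PopulationParams(alpha=3.0, beta=9.0, rates=(0.8,))
        t = np.linspace(0.5, 10, 8)
        rng = np.random.default_rng(3)
        z = rng.normal(0.3, 0.2, t.size)
        w = rng.uniform(0.5, 2.0, t.size)
        curve = make_curve(t, z, weights=w)
        basis = build_basis(curve, pop, 0.0)
        a = basis.values[:, 0]
        expected = max(0.0, float(np.sum(w * z * a) / np.sum(w * a * a)))
        assert fit_pi(curve, basis) == pytest.approx([expected], abs=1e-10)

    def test_matches_dense_grid_oracle(self, fdg_pop):
        """QP objective value matches a dense search over the feasible cone."""
        rng = np.random.default_rng(11)
        t = np.linspace(0.25, 40, 10)
        pi_star = np.array([3.0, 1.0, 0.5])
        z = evaluate_aif(t, fdg_pop, IndividualParams(pi=tuple(pi_star)), 1.0)
        z = z + rng.normal(0, 0.2, t.size)
        curve = make_curve(t, z)
        basis = build_basis(curve, fdg_pop, 0.0)
        pi_hat = fit_pi(curve, basis)

        def objective(p):
            r = z - basis.values @ p
            return float(np.sum(r * r))

        # dense refinement search around the solution, restricted to pi >= 0
        best = objective(pi_hat)
        for scale in (0.3, 0.05, 0.01):
            for _ in range(4000):
                cand = np.maximum(pi_hat + rng.normal(0, scale, 3), 0.0)
                best = min(best, objective(cand))
        assert objective(pi_hat) <= best + 1e-6 * abs(best)

    def test_kkt_conditions_hold(self, fdg_pop):
        rng = np.random.default_rng(4)
        t = np.linspace(0.25, 40, 14)
        z = np.abs(rng.normal(0.5, 0.5, t.size))
        curve = make_curve(t, z)
        basis = build_basis(curve, fdg_pop, 0.1)
        pi_hat = fit_pi(curve, basis)
        A = basis.values
        grad = -2.0 * A.T @ (z - A @ pi_hat)  # gradient of the LS objective
        # KKT: grad >= 0 everywhere, and = 0 on the active (positive) set
        assert np.all(grad >= -1e-6)
        assert grad[pi_hat > 1e-12] == pytest.approx(0.0, abs=1e-6)

    def test_ordering_constraint_enforced(self, fdg_pop):
        # data generated with pi2 > pi1; the constrained fit flips ordering
        t = np.linspace(0.25, 40, 20)
        z = evaluate_aif(t, fdg_pop, IndividualParams(pi=(0.5, 3.0, 0.5)), 1.0)
        curve = make_curve(t, z)
        basis = build_basis(curve, fdg_pop, 0.0)
        unconstrained = fit_pi(curve, basis)
        assert unconstrained[1] > unconstrained[0]
        constrained = fit_pi(curve, basis, ordering_constraint=True)
        assert constrained[0] >= constrained[1] - 1e-10

    def test_zero_basis_raises(self, fdg_pop):
        curve = make_curve([0.0, 0.05, 0.1], [0.0, 0.0, 0.0])
        basis = build_basis(curve, fdg_pop, 0.5)  # all samples precede delay
        with pytest.raises(ValueError, match="degenerate"):
            fit_pi(curve, basis)


# ---------------------------------------------------------------------------
# fit_delta: delay grid search
# ---------------------------------------------------------------------------

class TestFitDelta:
    def test_default_grid_spans_one_minute_window(self):
        grid = default_delta_grid()
        assert grid.size == 21
        assert grid[0] == -1.0 and grid[-1] == 1.0
        assert np.allclose(np.diff(grid), 0.1)

    def test_recovers_zero_delay(self, fdg_pop):
        t = np.linspace(0.25, 30, 15)
        z = evaluate_aif(t, fdg_pop, IndividualParams(pi=(5.0, 1.0, 0.2)), 1.0)
        d, pi, obj = fit_delta(make_curve(t, z), fdg_pop, grid=np.array([-1.0, 0.0, 1.0]))
        assert d == 0.0

    def test_recovers_on_grid_delay_exhaustively(self, fdg_pop):
        """The returned delay beats every other grid point's residual."""
        from pbpm.fit import _grid_profile
        t = np.asarray([0.25, 0.5, 0.75, 1, 1.5, 2, 3, 5, 8, 12, 20, 40, 60.0])
        truth = IndividualParams(pi=(5.0, 1.0, 0.2), delta=0.3)
        z = evaluate_aif(t, fdg_pop, truth, 1.0)
        curve = make_curve(t, z)
        d, pi, obj = fit_delta(curve, fdg_pop)
        assert d == pytest.approx(0.3)
        assert pi == pytest.approx([5.0, 1.0, 0.2], abs=1e-7)
        for delta in default_delta_grid():
            if abs(delta - 0.3) > 1e-9:
                other = _grid_profile(curve, fdg_pop.alpha, fdg_pop.beta,
                                      fdg_pop.rates, np.array([delta]))
                assert obj < other.objective

    def test_empty_grid_raises(self, fdg_pop):
        t = np.linspace(0.25, 5, 6)
        curve = make_curve(t, np.ones(6))
        with pytest.raises(ValueError, match="nonempty"):
            fit_delta(curve, fdg_pop, grid=np.array([]))

    def test_tied_objectives_break_toward_smallest_delay(self, fdg_pop):
        # all-zero data: every delay fits exactly with pi = 0, so the
        # deterministic tie-break must return the delay closest to zero
        t = np.asarray([2.0, 5.0, 10.0, 30.0])
        curve = make_curve(t, np.zeros(4))
        d, pi, obj = fit_delta(curve, fdg_pop)
        assert d == 0.0
        assert obj == 0.0


# ---------------------------------------------------------------------------
# fit_theta: population nonlinear step
# ---------------------------------------------------------------------------

class TestFitTheta:
    def test_logit_round_trip(self):
        lo = np.array([0.5, 0.1, 1e-3])
        hi = np.array([20.0, 60.0, 20.0])
        theta = np.array([3.0, 9.0, 0.5])
        back = inverse_logit_theta(logit_theta(theta, lo, hi), lo, hi)
        assert back == pytest.approx(theta, rel=1e-14)

    def test_theta0_outside_bounds_raises(self):
        with pytest.raises(ValueError, match="strictly inside"):
            logit_theta(np.array([0.5]), np.array([0.5]), np.array([2.0]))

    def test_noise_free_generative_consistency(self, noise_free_cohort):
        """Objective improves on theta0 and fits match data closely."""
        curves, truth = noise_free_cohort
        cfg = FitConfig.for_tracer("fdg", max_nfev=80)
        popfit = fit_theta(curves, cfg)
        from pbpm.fit import _grid_profile
        obj0 = 0.0
        th0 = cfg.theta0
        for c in curves:
            obj0 += _grid_profile(c, th0[0], th0[1], tuple(th0[2:]),
                                  cfg.delta_grid).objective
        assert popfit.objective <= obj0
        for c, f in zip(curves, popfit.per_subject):
            rmse = np.sqrt(np.mean((c.concentrations - f.fitted) ** 2))
            assert rmse <= 1e-4 * c.concentrations.max()

    def test_rates_returned_in_decreasing_order(self, trained_population):
        rates = np.asarray(trained_population.pop.rates)
        assert np.all(np.diff(rates) < 0)

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            fit_theta([], FitConfig.for_tracer("fdg"))


# ---------------------------------------------------------------------------
# Prior, regularization, GCV
# ---------------------------------------------------------------------------

class TestPopulationPrior:
    def test_identical_subjects(self):
        pis = np.tile([2.0, 1.0, 0.5], (4, 1))
        prior = population_prior(pis)
        assert prior.pi0 == pytest.approx([2.0, 1.0, 0.5])
        assert np.linalg.eigvalsh(prior.Omega).min() > 0  # conditioned
        assert np.abs(prior.Omega).max() < 1e-6

    def test_two_subjects_midpoint_and_rank(self):
        pis = np.array([[1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        prior = population_prior(pis)
        assert prior.pi0 == pytest.approx([2.0, 1.0, 1.0])
        raw = np.cov(pis, rowvar=False, ddof=1)
        assert np.linalg.matrix_rank(raw) == 1

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(9)
        pis = np.abs(rng.normal(2, 1, (10, 3)))
        prior = population_prior(pis)
        assert prior.pi0 == pytest.approx(pis.mean(axis=0))
        assert prior.Omega == pytest.approx(np.cov(pis, rowvar=False, ddof=1), abs=1e-7)

    def test_single_subject_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            population_prior(np.array([[1.0, 2.0]]))


@pytest.fixture(scope="module")
def shrinkage_setting(fdg_cohort, trained_population):
    curves, _ = fdg_cohort
    prior = population_prior(trained_population.pi_matrix())
    return curves[0], trained_population.pop, prior


class TestRegularizedFit:

    def test_lambda_zero_reproduces_unpenalized(self, shrinkage_setting):
        curve, pop, prior = shrinkage_setting
        reg = regularized_fit(curve, pop, replace(prior, lam=0.0))
        d, pi, obj = fit_delta(curve, pop)
        assert np.array_equal(np.asarray(reg.indiv.pi), pi)
        assert reg.indiv.delta == d
        assert reg.objective == obj

    def test_huge_lambda_pins_to_prior_mean(self, shrinkage_setting):
        curve, pop, prior = shrinkage_setting
        reg = regularized_fit(curve, pop, replace(prior, lam=1e9))
        assert np.max(np.abs(np.asarray(reg.indiv.pi) - prior.pi0)) < 1e-3

    def test_penalized_optimality_against_anchors(self, shrinkage_setting):
        """Penalized objective at the solution beats both pi0 and the
        unpenalized minimizer."""
        curve, pop, prior = shrinkage_setting
        lam = 1.0
        pr = replace(prior, lam=lam)
        reg = regularized_fit(curve, pop, pr)
        _, pi_unpen, _ = fit_delta(curve, pop)

        def penalized(pi, delta):
            from pbpm import basis_matrix_values
            A = basis_matrix_values(curve.times, pop, delta, curve.injection_duration)
            r = curve.concentrations - A @ pi
            d = pi - prior.pi0
            return (float(np.sum(curve.weights * r * r))
                    + lam * float(d @ np.linalg.solve(prior.Omega, d)))

        val = penalized(np.asarray(reg.indiv.pi), reg.indiv.delta)
        assert val <= penalized(prior.pi0, reg.indiv.delta) + 1e-9
        assert val <= penalized(pi_unpen, reg.indiv.delta) + 1e-9

    def test_monotone_shrinkage_along_lambda_ladder(self, shrinkage_setting):
        curve, pop, prior = shrinkage_setting
        grid = np.array([0.0])  # fixed delay isolates the shrinkage path
        dists = []
        for lam in np.logspace(-3, 6, 12):
            reg = regularized_fit(curve, pop, replace(prior, lam=lam), delta_grid=grid)
            dists.append(np.linalg.norm(np.asarray(reg.indiv.pi) - prior.pi0))
        assert np.all(np.diff(dists) <= 1e-9)


class TestGCV:
    def test_low_lambda_effective_dof(self, fdg_cohort, trained_population):
        """lambda -> 0: denominator -> ((m - J)/m)^2 for full-rank basis."""
        curves, _ = fdg_cohort
        curve = curves[1]
        pop = trained_population.pop
        from pbpm import basis_matrix_values
        A = basis_matrix_values(curve.times, pop, 0.0, curve.injection_duration)
        z = curve.concentrations
        fitted = A @ np.linalg.lstsq(A, z, rcond=None)[0]
        m, J = A.shape
        score = gcv_score(curve, A, fitted, 0.0)
        expected = np.mean((z - fitted) ** 2) / ((m - J) / m) ** 2
        assert score == pytest.approx(expected, rel=1e-8)

    def test_matches_direct_matrix_evaluation(self, fdg_cohort, trained_population):
        curves, _ = fdg_cohort
        curve = curves[2]
        pop = trained_population.pop
        prior = population_prior(trained_population.pi_matrix())
        lam = 0.5
        fit = regularized_fit(curve, pop, replace(prior, lam=lam))
        from pbpm import basis_matrix_values
        A = basis_matrix_values(curve.times, pop, fit.indiv.delta,
                                curve.injection_duration)
        m = curve.m
        H = A @ np.linalg.inv(A.T @ A + m * lam * np.eye(A.shape[1])) @ A.T
        denom = (np.trace(np.eye(m) - H) / m) ** 2
        expected = np.mean((curve.concentrations - fit.fitted) ** 2) / denom
        assert gcv_score(curve, A, fit.fitted, lam) == pytest.approx(expected, rel=1e-9)

    def test_empty_lambda_grid_raises(self, fdg_cohort, trained_population):
        curves, _ = fdg_cohort
        prior = population_prior(trained_population.pi_matrix())
        with pytest.raises(ValueError, match="nonempty"):
            gcv_select_lambda(curves[0], trained_population.pop, prior,
                              lambda_grid=np.array([]))


# ---------------------------------------------------------------------------
# fit_new_patient
# ---------------------------------------------------------------------------

class TestFitNewPatient:
    def test_noise_free_exact_recovery(self, fdg_pop):
        frame = np.asarray([0.25, 0.5, 0.75, 1, 1.5, 2, 3, 5, 8, 12, 20, 40, 60.0])
        truth = IndividualParams(pi=(4.2, 0.8, 0.35), delta=-0.2)
        z = evaluate_aif(frame, fdg_pop, truth, 1.0)
        res = fit_new_patient(make_curve(frame, z), fdg_pop)
        assert res.indiv.delta == pytest.approx(-0.2)
        assert res.indiv.pi == pytest.approx(truth.pi, abs=1e-6)

    def test_population_parameters_untouched(self, trained_population, fdg_cohort):
        curves, _ = fdg_cohort
        pop = trained_population.pop
        theta_before = pop.theta().copy()
        fit_new_patient(curves[3], pop)
        assert pop.theta() == pytest.approx(theta_before, rel=0)
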