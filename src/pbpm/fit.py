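"""Nested estimation for the population-based projection AIF model.

The fitting procedure profiles parameters in three nested layers:

* **pi | (delta, theta)** — weighted, positivity-constrained least squares
  (a convex quadratic program, solved exactly by reduction to NNLS);
* **delta | theta** — exhaustive grid search over a delay window,
  re-solving the pi-problem at each candidate delay;
* **theta** — bounded nonlinear least squares of the population objective
  ``l(theta) = sum_k sum_i w_ik (z_ik - C_P(t_ik | delta_k, pi_k, theta))^2``
  with (delta_k, pi_k) re-profiled at every theta evaluation, run
  unconstrained on a logit-transformed scale.

For subjects outside the training cohort the trained ``theta`` is reused
and only (pi, delta) are estimated, optionally with a quadratic penalty
``lambda (pi - pi0)' Omega^-1 (pi - pi0)`` that shrinks the individual
weights toward the population mean; the penalty weight is chosen by
generalized cross-validation (GCV).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

from .aif_core import (GRID_STEP_MIN, IndividualParams, PopulationParams,
                       SamplingCurve, _grid_for)
from .presets import TracerPreset, get_preset

__all__ = [
    "BasisMatrix",
    "RegularizationPrior",
    "FitResult",
    "PopulationFit",
    "FitConfig",
    "default_delta_grid",
    "default_lambda_grid",
    "build_basis",
    "fit_pi",
    "fit_delta",
    "fit_theta",
    "population_prior",
    "regularized_fit",
    "gcv_select_lambda",
    "fit_new_patient",
    "logit_theta",
    "inverse_logit_theta",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types and defaults
# ---------------------------------------------------------------------------

@dataclass
class BasisMatrix:
    """Basis components evaluated at one subject's sample times."""

    values: np.ndarray          # m x J, entries A_ij
    times: np.ndarray
    delta: float
    pop: PopulationParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("basis entries must be finite and nonnegative")


@dataclass
class RegularizationPrior:
    """Population shrinkage prior: mean ``pi0``, covariance ``Omega``, weight ``lam``."""

    pi0: np.ndarray
    Omega: np.ndarray
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.pi0 = np.asarray(self.pi0, dtype=float)
        self.Omega = np.atleast_2d(np.asarray(self.Omega, dtype=float))
        if np.any(self.pi0 < 0):
            raise ValueError("pi0 must be nonnegative")
        if self.Omega.shape != (self.pi0.size, self.pi0.size):
            raise ValueError("Omega shape does not match pi0")
        if not np.allclose(self.Omega, self.Omega.T):
            raise ValueError("Omega must be symmetric")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


@dataclass
class FitResult:
    """Outcome of an individual (pi, delta) fit."""

    indiv: IndividualParams
    objective: float            # weighted residual sum of squares
    fitted: np.ndarray          # model values at the sample times
    lambda_used: float = 0.0
    converged: bool = True
    penalized_objective: float | None = None


@dataclass
class PopulationFit:
    """Outcome of population training: shared theta plus per-subject fits."""

    pop: PopulationParams
    per_subject: list[FitResult]
    objective: float
    converged: bool
    n_evaluations: int = 0

    def pi_matrix(self) -> np.ndarray:
        return np.array([f.indiv.pi for f in self.per_subject])


def default_delta_grid() -> np.ndarray:
    """21 evenly spaced delays spanning -60 s .. +60 s, in minutes."""
    return np.linspace(-1.0, 1.0, 21)


def default_lambda_grid() -> np.ndarray:
    """GCV ladder: 0 plus a 15-point logarithmic ladder 1e-4 .. 1e3."""
    return np.concatenate([[0.0], np.logspace(-4, 3, 15)])


@dataclass
class FitConfig:
    """Bundled configuration for the nested fitting procedure."""

    J: int
    theta0: np.ndarray
    theta_lo: np.ndarray
    theta_hi: np.ndarray
    delta_grid: np.ndarray = field(default_factory=default_delta_grid)
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    ordering_constraint: bool = False
    max_nfev: int = 200
    ftol: float = 1e-8

    @classmethod
    def for_tracer(cls, tracer: str | TracerPreset, J: int | None = None,
                   **overrides) -> "FitConfig":
        preset = get_preset(tracer) if isinstance(tracer, str) else tracer
        if J is not None and J != preset.J:
            preset = replace(preset, J=J)
        lo, hi = preset.theta_bounds()
        cfg = cls(J=preset.J, theta0=preset.theta0(), theta_lo=lo, theta_hi=hi)
        for key, val in overrides.items():
            setattr(cfg, key, val)
        return cfg


# ---------------------------------------------------------------------------
# Constrained linear step: pi | (delta, theta)
# ---------------------------------------------------------------------------

def _ordering_map(J: int) -> np.ndarray:
    """Reparametrization matrix M with pi = M u, u >= 0  <=>  pi >= 0, pi1 >= pi2."""
    M = np.eye(J)
    M[0, 1] = 1.0  # pi1 = u1 + u2, pi2 = u2
    return M


try:  # low-overhead entry point to the same active-set routine; the
    # public wrapper spends more time on input checking than solving
    # these small (m x J) problems
    from scipy.optimize._slsqplib import nnls as _nnls_core

    def _nnls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
        x, _, info = _nnls_core(np.ascontiguousarray(A, dtype=np.float64),
                                np.ascontiguousarray(b, dtype=np.float64),
                                10 * A.shape[1])
        if info != 1:  # pragma: no cover - tiny well-posed systems converge
            x, _ = optimize.nnls(A, b)
        return x
except ImportError:  # pragma: no cover
    def _nnls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
        return optimize.nnls(A, b)[0]


def _solve_nnls(A: np.ndarray, b: np.ndarray, ordering: bool) -> np.ndarray:
    """Exact minimizer of ||A pi - b||^2 over the constrained cone.

    The positivity-constrained QP is solved by NNLS (an active-set method
    equivalent to Goldfarb-Idnani for this problem class); the ordering
    constraint pi1 >= pi2 is folded in by a nonnegative reparametrization.
    """
    if ordering and A.shape[1] >= 2:
        M = _ordering_map(A.shape[1])
        u = _nnls(A @ M, b)
        return M @ u
    return _nnls(A, b)


def build_basis(curve: SamplingCurve, pop: PopulationParams, delta: float) -> BasisMatrix:
    """Basis matrix ``A`` with ``A[i, j] = A_j(t_i | delta, theta)``."""
    from .aif_core import basis_matrix_values
    values = basis_matrix_values(curve.times, pop, delta, curve.injection_duration)
    return BasisMatrix(values=values, times=curve.times, delta=delta, pop=pop)


def fit_pi(curve: SamplingCurve, basis: BasisMatrix,
           ordering_constraint: bool = False) -> np.ndarray:
    """Weighted positivity-constrained least-squares estimate of pi.

    Minimizes ``sum_i w_i (z_i - sum_j pi_j A_ij)^2`` subject to
    ``pi >= 0`` (and optionally ``pi_1 >= pi_2``).
    """
    if basis.values.shape[0] != curve.m:
        raise ValueError("basis was not built from this curve's times")
    if not np.any(basis.values):
        raise ValueError("degenerate design: basis matrix is identically zero")
    sw = np.sqrt(curve.weights)
    return _solve_nnls(sw[:, None] * basis.values, sw * curve.concentrations,
                       ordering_constraint)


# ---------------------------------------------------------------------------
# Grid-profiled individual fit (shared by the plain and penalized paths)
# ---------------------------------------------------------------------------

def _penalty_root(prior: RegularizationPrior) -> np.ndarray:
    """Matrix R with R'R = Omega^-1 (upper Cholesky of the inverse)."""
    Oinv = np.linalg.inv(prior.Omega)
    Oinv = 0.5 * (Oinv + Oinv.T)
    C = np.linalg.cholesky(Oinv)
    return C.T


def _grid_profile(curve: SamplingCurve, alpha, beta, rates, delta_grid,
                  prior: RegularizationPrior | None = None,
                  ordering: bool = False,
                  stack: np.ndarray | None = None) -> FitResult:
    """Profile (pi, delta) on the delay grid for fixed nonlinear parameters.

    Selects the grid delay with the smallest (penalized) objective; ties
    within 1e-12 (relative) break toward the delay closest to zero so that
    output is deterministic.  ``stack`` may carry precomputed per-delay
    basis matrices (shape ``(len(delta_grid), m, J)``) so that cohorts
    sharing a sampling frame evaluate the basis once per theta.
    """
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid.size == 0:
        raise ValueError("delay grid must be nonempty")
    t = curve.times
    z = curve.concentrations
    sw = np.sqrt(curve.weights)

    lam = 0.0 if prior is None else float(prior.lam)
    if prior is not None and lam > 0:
        R = _penalty_root(prior)
        pen_rows = math.sqrt(lam) * R
        pen_rhs = pen_rows @ prior.pi0

    if stack is None:
        stack = _basis_stack(curve, alpha, beta, rates, delta_grid)
    best = None
    for delta, A in zip(delta_grid, stack):
        if not np.any(A):
            continue
        Aw = sw[:, None] * A
        bw = sw * z
        if prior is not None and lam > 0:
            pi = _solve_nnls(np.vstack([Aw, pen_rows]),
                             np.concatenate([bw, pen_rhs]), ordering)
        else:
            pi = _solve_nnls(Aw, bw, ordering)
        fitted = A @ pi
        wrss = float(np.sum(curve.weights * (z - fitted) ** 2))
        obj = wrss
        if prior is not None and lam > 0:
            d = pi - prior.pi0
            obj = wrss + lam * float(d @ np.linalg.solve(prior.Omega, d))
        cand = (obj, abs(delta), delta, pi, fitted, wrss)
        if best is None:
            best = cand
        else:
            tol = 1e-12 * max(1.0, abs(best[0]))
            if cand[0] < best[0] - tol:
                best = cand
            elif abs(cand[0] - best[0]) <= tol and cand[1] < best[1]:
                best = cand
    if best is None:
        raise ValueError(f"{curve.subject_id}: basis is zero at every grid delay "
                         "(all sample times precede the delayed injection?)")
    obj, _, delta, pi, fitted, wrss = best
    return FitResult(indiv=IndividualParams(pi=tuple(pi), delta=float(delta)),
                     objective=wrss, fitted=fitted, lambda_used=lam,
                     penalized_objective=obj)


def _basis_stack(curve: SamplingCurve, alpha, beta, rates,
                 delta_grid: np.ndarray) -> np.ndarray:
    """Per-delay basis matrices for one curve at fixed nonlinear parameters."""
    from .aif_core import _eval_delayed_stack
    t = curve.times
    tmax = float(t.max()) - min(0.0, float(np.min(delta_grid)))
    tg, B = _grid_for(alpha, beta, rates, curve.injection_duration, tmax)
    return _eval_delayed_stack(tg, B, rates, t, delta_grid)


def fit_delta(curve: SamplingCurve, pop: PopulationParams,
              grid: np.ndarray | None = None,
              ordering_constraint: bool = False) -> tuple[float, np.ndarray, float]:
    """Grid search for the delay: returns ``(delta_hat, pi_hat, objective)``.

    The objective is ``l2(delta | theta) = l1(pi_hat(delta) | delta, theta)``,
    minimized exhaustively over the grid.
    """
    res = _grid_profile(curve, pop.alpha, pop.beta, pop.rates,
                        default_delta_grid() if grid is None else grid,
                        ordering=ordering_constraint)
    return res.indiv.delta, np.asarray(res.indiv.pi), res.objective


# ---------------------------------------------------------------------------
# Population nonlinear step: theta
# ---------------------------------------------------------------------------

def logit_theta(theta, lo, hi) -> np.ndarray:
    """Map theta strictly inside (lo, hi) to the unconstrained logit scale."""
    theta, lo, hi = (np.asarray(a, dtype=float) for a in (theta, lo, hi))
    p = (theta - lo) / (hi - lo)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("theta must lie strictly inside (lo, hi)")
    return np.log(p / (1.0 - p))

def inverse_logit_theta(zeta, lo, hi) -> np.ndarray:
    """Inverse of :func:`logit_theta`."""
    zeta, lo, hi = (np.asarray(a, dtype=float) for a in (zeta, lo, hi))
    return lo + (hi - lo) * special.expit(zeta)


def fit_theta(cohort: list[SamplingCurve], config: FitConfig,
              theta_init: np.ndarray | None = None) -> PopulationFit:
    """Estimate the population parameters theta on a training cohort.

    Minimizes the pooled weighted residual sum of squares with the
    per-subject (delta_k, pi_k) re-profiled (grid search + constrained
    least squares) at every theta evaluation.  The optimization runs
    unconstrained on the logit scale with a trust-region Gauss-Newton
    method and numerical Jacobians.  ``theta_init`` overrides the
    configured starting point (e.g. to warm-start cross-validation folds);
    it is nudged strictly inside the bounds if it touches them.
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    lo = np.asarray(config.theta_lo, dtype=float)
    hi = np.asarray(config.theta_hi, dtype=float)
    if theta_init is None:
        theta0 = np.asarray(config.theta0, dtype=float)
    else:
        margin = 1e-6 * (hi - lo)
        theta0 = np.minimum(np.maximum(np.asarray(theta_init, dtype=float),
                                       lo + margin), hi - margin)
    if theta0.size != 2 + config.J:
        raise ValueError(f"theta0 must have length {2 + config.J}")
    if np.any(theta0 <= lo) or np.any(theta0 >= hi):
        raise ValueError("theta0 must lie strictly inside (theta_lo, theta_hi)")

    n_eval = 0

    def residuals(zeta: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        theta = inverse_logit_theta(zeta, lo, hi)
        alpha, beta, rates = theta[0], theta[1], tuple(theta[2:])
        out = []
        stacks: dict[tuple, np.ndarray] = {}  # subjects often share a frame
        for curve in cohort:
            key = (curve.times.tobytes(), curve.injection_duration)
            stack = stacks.get(key)
            if stack is None:
                stack = _basis_stack(curve, alpha, beta, rates, config.delta_grid)
                stacks[key] = stack
            res = _grid_profile(curve, alpha, beta, rates, config.delta_grid,
                                ordering=config.ordering_constraint, stack=stack)
            out.append(np.sqrt(curve.weights) * (curve.concentrations - res.fitted))
        return np.concatenate(out)

    zeta0 = logit_theta(theta0, lo, hi)
    sol = optimize.least_squares(residuals, zeta0, method="trf",
                                 ftol=config.ftol, xtol=1e-10,
                                 max_nfev=config.max_nfev)
    theta = inverse_logit_theta(sol.x, lo, hi)
    alpha, beta = float(theta[0]), float(theta[1])
    rates = np.sort(theta[2:])[::-1]  # restore identifiability ordering
    # break exact ties (degenerate but possible at bound saturation)
    for i in range(1, rates.size):
        if rates[i] >= rates[i - 1]:
            rates[i] = rates[i - 1] * (1.0 - 1e-9)
    pop = PopulationParams(alpha=alpha, beta=beta, rates=tuple(rates))

    per_subject = []
    total = 0.0
    for curve in cohort:
        res = _grid_profile(curve, pop.alpha, pop.beta, pop.rates,
                            config.delta_grid, ordering=config.ordering_constraint)
        per_subject.append(res)
        total += res.objective
    converged = sol.status > 0
    if not converged:
        logger.warning("fit_theta did not converge (status %d): %s",
                       sol.status, sol.message)
    logger.debug("fit_theta: %d evaluations, objective %.6g, theta=%s",
                 n_eval, total, np.round(pop.theta(), 4))
    return PopulationFit(pop=pop, per_subject=per_subject, objective=total,
                         converged=converged, n_evaluations=n_eval)


# ---------------------------------------------------------------------------
# Shrinkage prior and penalized individual fitting
# ---------------------------------------------------------------------------

def population_prior(pis: np.ndarray | list, lam: float = 0.0) -> RegularizationPrior:
    """Mean and covariance of training mixing weights, conditioned to be
    positive definite (ridge ``eps*I`` with ``eps = 1e-8 trace/J`` when the
    smallest eigenvalue falls below it).
    """
    P = np.atleast_2d(np.asarray(pis, dtype=float))
    if P.shape[0] < 2:
        raise ValueError("need at least 2 training subjects for a prior")
    pi0 = P.mean(axis=0)
    Omega = np.atleast_2d(np.cov(P, rowvar=False, ddof=1))
    J = pi0.size
    tr = float(np.trace(Omega))
    eps = 1e-8 * tr / J if tr > 0 else 1e-10
    if np.linalg.eigvalsh(Omega).min() < eps:
        Omega = Omega + eps * np.eye(J)
    return RegularizationPrior(pi0=pi0, Omega=Omega, lam=lam)


def regularized_fit(curve: SamplingCurve, pop: PopulationParams,
                    prior: RegularizationPrior,
                    delta_grid: np.ndarray | None = None,
                    ordering_constraint: bool = False) -> FitResult:
    """Penalized individual fit: minimizes, over the delay grid and pi >= 0,

        f_lam(pi | delta) = sum_i w_i (z_i - (A pi)_i)^2
                            + lam (pi - pi0)' Omega^-1 (pi - pi0).

    ``lam = 0`` reproduces the unpenalized grid fit exactly.
    """
    grid = default_delta_grid() if delta_grid is None else delta_grid
    return _grid_profile(curve, pop.alpha, pop.beta, pop.rates, grid,
                         prior=prior, ordering=ordering_constraint)


def gcv_score(curve: SamplingCurve, A: np.ndarray, fitted: np.ndarray,
              lam: float) -> float:
    """Generalized cross-validation score at one penalty weight.

    Mean squared error divided by the squared effective-degrees-of-freedom
    fraction ``trace(I - A (A'A + m lam I)^-1 A') / m``.
    """
    z = curve.concentrations
    m = curve.m
    mse = float(np.mean((z - fitted) ** 2))
    AtA = A.T @ A
    H_core = np.linalg.pinv(AtA + m * lam * np.eye(A.shape[1]))
    edf_frac = 1.0 - float(np.trace(A @ H_core @ A.T)) / m
    return mse / edf_frac ** 2


def gcv_select_lambda(curve: SamplingCurve, pop: PopulationParams,
                      prior: RegularizationPrior,
                      lambda_grid: np.ndarray | None = None,
                      delta_grid: np.ndarray | None = None,
                      ordering_constraint: bool = False
                      ) -> tuple[float, FitResult]:
    """Choose the shrinkage weight minimizing the GCV score.

    Higher-noise curves favor larger penalties, pulling the individual
    weights toward the population mean.
    """
    lams = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if lams.size == 0:
        raise ValueError("lambda grid must be nonempty")
    dgrid = default_delta_grid() if delta_grid is None else delta_grid
    best_lam, best_fit, best_score = None, None, np.inf
    for lam in lams:
        fit = _grid_profile(curve, pop.alpha, pop.beta, pop.rates, dgrid,
                            prior=replace(prior, lam=float(lam)),
                            ordering=ordering_constraint)
        from .aif_core import basis_matrix_values
        A = basis_matrix_values(curve.times, pop, fit.indiv.delta,
                                curve.injection_duration)
        score = gcv_score(curve, A, fit.fitted, float(lam))
        if score < best_score:
            best_lam, best_fit, best_score = float(lam), fit, score
    return best_lam, best_fit


def fit_new_patient(curve: SamplingCurve, pop: PopulationParams,
                    prior: RegularizationPrior | None = None,
                    delta_grid: np.ndarray | None = None,
                    lambda_grid: np.ndarray | None = None,
                    ordering_constraint: bool = False) -> FitResult:
    """Fit a subject outside the training cohort, reusing trained theta.

    Without a prior this is the plain grid-profiled fit; with a prior the
    shrinkage weight is selected by GCV.  The population parameters are
    never re-estimated.
    """
    if prior is None:
        return _grid_profile(curve, pop.alpha, pop.beta, pop.rates,
                             default_delta_grid() if delta_grid is None else delta_grid,
                             ordering=ordering_constraint)
    _, fit = gcv_select_lambda(curve, pop, prior, lambda_grid=lambda_grid,
                               delta_grid=delta_grid,
                               ordering_constraint=ordering_constraint)
    return fit
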