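"""Forward model for population-based projection of arterial input functions.

The arterial input function (AIF) is the time course of tracer activity
concentration in arterial plasma that drives kinetic models of dynamic PET
data.  The model represented here decomposes the travel time of a tracer
atom into two stages:

1. injection site to the right ventricle, modeled as a Gamma(alpha, beta)
   random variable, convolved with the injection profile (a boxcar of the
   stated injection duration) to give the right-ventricle concentration
   profile ``C_RV(t)``;
2. circulation from the right ventricle to the sampling site, modeled as a
   site-specific shift ``delta`` plus an *excess circulation time* whose
   density is approximated by a mixture of exponential densities with
   population-shared rates ``phi_1 > phi_2 > ... > phi_J``.

The model AIF is the linear combination of basis components

    C_P(t) = sum_j pi_j * A_j(t | delta, theta),
    A_j(t) = int_0^t phi_j exp(-phi_j (t - s)) * C_RV(s - delta) ds,

where the nonnegative mixing weights ``pi`` and the delay ``delta`` are
subject-specific while ``theta = (alpha, beta, phi_1..phi_J)`` is shared
across the population.

All times are in minutes and all rates in 1/minute.  The boxcar injection
profile is normalized to unit area (height ``1/duration``) so that mixing
weights are comparable across injection protocols of different durations;
the absolute activity scale is carried by ``pi`` and by the separate scale
factor model (see :mod:`pbpm.scaling`).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, special

__all__ = [
    "GRID_STEP_MIN",
    "SamplingCurve",
    "PopulationParams",
    "IndividualParams",
    "injection_profile",
    "basis_component",
    "basis_matrix_values",
    "evaluate_aif",
]

#: Internal convolution grid step (minutes); 0.125 s resolves the sharpest
#: physiologic injection transients while keeping grids small.
GRID_STEP_MIN = 1.0 / 480.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationParams:
    """Population-shared nonlinear AIF parameters ``theta``.

    Parameters
    ----------
    alpha, beta
        Shape and rate (1/min) of the Gamma travel-time distribution for
        the injection-site-to-right-ventricle stage.
    rates
        Exponential rates ``(phi_1, ..., phi_J)`` in 1/min, strictly
        decreasing (identifiability ordering).
    """

    alpha: float
    beta: float
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and positive, got {self.alpha}")
        if not (math.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite and positive, got {self.beta}")
        r = np.asarray(self.rates, dtype=float)
        if r.size < 1:
            raise ValueError("at least one exponential rate is required")
        if not np.all(np.isfinite(r)) or not np.all(r > 0):
            raise ValueError("rates must be finite and positive")
        if r.size > 1 and not np.all(np.diff(r) < 0):
            raise ValueError(f"rates must be strictly decreasing, got {self.rates}")

    @property
    def J(self) -> int:
        """Number of mixture components."""
        return len(self.rates)

    def theta(self) -> np.ndarray:
        """Parameter vector ``(alpha, beta, phi_1..phi_J)``."""
        return np.concatenate([[self.alpha, self.beta], self.rates])


@dataclass(frozen=True)
class IndividualParams:
    """Subject-specific AIF parameters: mixing weights and delay.

    ``pi`` are nonnegative, unitless weights of the exponential basis;
    ``delta`` is the sampling-site delay in minutes (may be negative when
    the recorded injection time lags the true one).
    """

    pi: tuple[float, ...]
    delta: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi", tuple(float(p) for p in self.pi))
        p = np.asarray(self.pi, dtype=float)
        if p.size < 1 or not np.all(np.isfinite(p)):
            raise ValueError("pi must be a nonempty finite vector")
        if np.any(p < 0):
            raise ValueError(f"mixing weights must be nonnegative, got {self.pi}")
        if not math.isfinite(self.delta):
            raise ValueError("delta must be finite")

    @property
    def J(self) -> int:
        return len(self.pi)


@dataclass
class SamplingCurve:
    """One subject's measured blood time course.

    ``times`` (min, strictly increasing), ``concentrations`` (arbitrary
    activity units) and ``weights`` (positive reliability weights) all
    have the same length ``m >= 3``.  ``injection_duration`` is the boxcar
    width in minutes.
    """

    subject_id: str
    times: np.ndarray
    concentrations: np.ndarray
    injection_duration: float
    weights: np.ndarray | None = None
    tracer: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.weights is None:
            self.weights = np.ones_like(self.times)
        self.weights = np.asarray(self.weights, dtype=float)
        m = self.times.size
        if m < 3:
            raise ValueError(f"{self.subject_id}: need at least 3 samples, got {m}")
        if self.concentrations.size != m or self.weights.size != m:
            raise ValueError(f"{self.subject_id}: times/concentrations/weights length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.subject_id}: sample times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError(f"{self.subject_id}: sample times must be nonnegative")
        if not np.all(np.isfinite(self.concentrations)):
            raise ValueError(f"{self.subject_id}: concentrations must be finite")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError(f"{self.subject_id}: weights must be positive")
        if not (math.isfinite(self.injection_duration) and self.injection_duration > 0):
            raise ValueError(f"{self.subject_id}: injection_duration must be positive")

    @property
    def m(self) -> int:
        """Number of samples."""
        return self.times.size


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def injection_profile(t, alpha: float, beta: float, duration: float) -> np.ndarray:
    """Right-ventricle concentration profile ``C_RV(t) = G (x) I(t)``.

    Convolution of the Gamma(alpha, beta) travel-time density with a
    unit-area boxcar of width ``duration``; evaluated analytically as a
    difference of Gamma CDFs:

        C_RV(t) = (F_G(t) - F_G(t - duration)) / duration.

    Nonnegative, zero for ``t <= 0``, integrates to 1 over all t.
    """
    if not (alpha > 0 and beta > 0):
        raise ValueError(f"alpha and beta must be positive, got {(alpha, beta)}")
    if not duration > 0:
        raise ValueError(f"duration must be positive, got {duration}")
    t = np.asarray(t, dtype=float)
    # regularized lower incomplete gamma == Gamma(alpha, beta) CDF at rate
    # parametrization; clamped at zero for pre-injection times
    upper = special.gammainc(alpha, beta * np.maximum(t, 0.0))
    lower = special.gammainc(alpha, beta * np.maximum(t - duration, 0.0))
    return (upper - lower) / duration


def _exp_kernel_convolve(values: np.ndarray, rate: float, step: float) -> np.ndarray:
    """Convolve ``rate * exp(-rate u)`` with the piecewise-linear interpolant
    of ``values`` sampled on a uniform grid of spacing ``step``.

    The exponential kernel is treated exactly over each step (the linear
    recurrence is evaluated with a C-level IIR filter), so the only error
    is the piecewise-linear approximation of the integrand.
    """
    x = rate * step
    E = math.exp(-x)
    if x > 1e-6:
        c = (1.0 - E * (1.0 + x)) / x
    else:  # series expansion, avoids catastrophic cancellation
        c = x / 2.0 - x * x / 3.0
    w1 = (1.0 - E) - c
    w0 = c
    inc = np.empty_like(values)
    inc[0] = 0.0
    inc[1:] = w0 * values[:-1] + w1 * values[1:]
    return signal.lfilter([1.0], [1.0, -E], inc)


@functools.lru_cache(maxsize=16)
def _crv_grid(alpha: float, beta: float, duration: float,
              n_steps: int, step: float) -> np.ndarray:
    """Injection profile C_RV on a uniform fine grid, cached separately
    from the rates so that rate-only parameter perturbations (e.g. in
    numerical Jacobians) reuse the Gamma CDF evaluation.
    """
    t = np.arange(n_steps + 1) * step
    F = special.gammainc(alpha, beta * t)
    shift = duration / step
    k = int(round(shift))
    if abs(shift - k) < 1e-9 and 0 < k <= n_steps:
        # boxcar width is a whole number of grid steps: the lower CDF is
        # the upper one shifted, saving a second incomplete-gamma sweep
        lower = np.concatenate([np.zeros(k), F[:-k]])
    else:
        lower = special.gammainc(alpha, beta * np.maximum(t - duration, 0.0))
    crv = (F - lower) / duration
    crv.setflags(write=False)
    return crv


@functools.lru_cache(maxsize=64)
def _basis_grid(alpha: float, beta: float, rates: tuple[float, ...],
                duration: float, n_steps: int, step: float):
    """Undelayed basis components ``A_j(t | delta=0)`` on a uniform fine grid.

    Returns ``(t_grid, B)`` with ``B[i, j] = A_{j+1}(t_grid[i])``.  A delay
    only shifts the time argument (``A_j(t | delta) = A_j(t - delta | 0)``),
    so one cached grid serves every delay on the search grid.
    """
    t = np.arange(n_steps + 1) * step
    crv = _crv_grid(alpha, beta, duration, n_steps, step)
    B = np.column_stack([_exp_kernel_convolve(crv, phi, step) for phi in rates])
    t.setflags(write=False)
    B.setflags(write=False)
    return t, B


def _grid_for(alpha, beta, rates, duration, tmax, step=GRID_STEP_MIN):
    # round the grid end up to a whole minute so repeated calls with the
    # same frame hit the cache
    end = max(1.0, math.ceil(tmax + step))
    n_steps = int(math.ceil(end / step))
    return _basis_grid(float(alpha), float(beta), tuple(float(r) for r in rates),
                       float(duration), n_steps, float(step))


def _interp_uniform_cubic(xq, step: float, Y: np.ndarray) -> np.ndarray:
    """Catmull-Rom interpolation of samples ``Y`` on the uniform grid
    ``0, step, 2*step, ...``; linear in the edge cells, zero left of 0.

    The basis curves bend sharply at the injection rise, where linear
    interpolation at the (few) requested sample times would dominate the
    evaluation error.
    """
    xq = np.asarray(xq, dtype=float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    out = _interp_uniform_cubic_cols(xq, step, Y2)
    return out[:, 0] if Y.ndim == 1 else out


def _interp_uniform_cubic_cols(xq, step: float, Y: np.ndarray) -> np.ndarray:
    """Vectorized Catmull-Rom interpolation of every column of ``Y``.

    One set of query indices serves all columns, which keeps the inner
    loop of the delay grid search cheap.
    """
    n = Y.shape[0]
    pos = np.minimum(np.maximum(xq / step, 0.0), n - 1.0)
    i = np.minimum(np.maximum(pos.astype(np.intp), 1), n - 3)
    u = (pos - i)[:, None]
    P0, P1, P2, P3 = Y[i - 1], Y[i], Y[i + 1], Y[i + 2]
    cubic = P1 + 0.5 * u * (P2 - P0 + u * (2 * P0 - 5 * P1 + 4 * P2 - P3
                                           + u * (3 * (P1 - P2) + P3 - P0)))
    i0 = np.minimum(pos.astype(np.intp), n - 2)
    lin = Y[i0] + (pos - i0)[:, None] * (Y[i0 + 1] - Y[i0])
    edge = ((pos < 1.0) | (pos > n - 3.0))[:, None]
    out = np.where(edge, lin, cubic)
    out[xq < 0.0] = 0.0
    return out


def _eval_delayed_matrix(tg, B, rates, t, delta) -> np.ndarray:
    """Delayed basis components (all columns) from undelayed grid values.

    The model integral starts at s = 0, so a negative delay must not pick
    up tracer circulating before the clock started; that early segment is
    removed by the exact correction ``A0_j(-delta) * exp(-phi_j t)`` per
    component (zero for nonnegative delays).
    """
    step = tg[1] - tg[0]
    vals = _interp_uniform_cubic_cols(t - delta, step, B)
    if delta < 0:
        heads = _interp_uniform_cubic_cols(np.array([-delta]), step, B)[0]
        decay = np.exp(-np.outer(np.maximum(t, 0.0), np.asarray(rates, dtype=float)))
        vals = vals - heads[None, :] * decay
    vals[t <= max(delta, 0.0), :] = 0.0
    return np.maximum(vals, 0.0)


def _eval_delayed_column(tg, col, phi, t, delta) -> np.ndarray:
    """Single delayed basis component; see :func:`_eval_delayed_matrix`."""
    return _eval_delayed_matrix(tg, col[:, None], (phi,), t, delta)[:, 0]


def _eval_delayed_stack(tg, B, rates, t, deltas) -> np.ndarray:
    """Basis matrices for every delay of a search grid in one pass.

    Returns an array of shape ``(len(deltas), len(t), J)``; one big
    interpolation gather replaces a per-delay loop in the grid search.
    """
    step = tg[1] - tg[0]
    deltas = np.asarray(deltas, dtype=float)
    t = np.asarray(t, dtype=float)
    D, m = deltas.size, t.size
    queries = (t[None, :] - deltas[:, None]).ravel()
    vals = _interp_uniform_cubic_cols(queries, step, B).reshape(D, m, B.shape[1])
    neg = deltas < 0
    if np.any(neg):
        heads = _interp_uniform_cubic_cols(-deltas[neg], step, B)
        decay = np.exp(-np.outer(np.maximum(t, 0.0), np.asarray(rates, dtype=float)))
        vals[neg] -= heads[:, None, :] * decay[None, :, :]
    mask = t[None, :] <= np.maximum(deltas, 0.0)[:, None]
    vals[mask] = 0.0
    return np.maximum(vals, 0.0)


def basis_component(t, j: int, params: PopulationParams, delta: float,
                    duration: float, step: float = GRID_STEP_MIN) -> np.ndarray:
    """Evaluate the j-th (1-based) basis component ``A_j(t | delta, theta)``.

    ``A_j`` is the convolution of the exponential density with rate
    ``phi_j`` and the delayed injection profile; it is zero for
    ``t <= delta`` (causality) and continuous in ``t``.
    """
    if not 1 <= j <= params.J:
        raise IndexError(f"component index {j} out of range 1..{params.J}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tmax = float(np.max(t)) - min(0.0, delta)
    tg, B = _grid_for(params.alpha, params.beta, params.rates, duration, tmax, step)
    return _eval_delayed_column(tg, B[:, j - 1], params.rates[j - 1], t, delta)


def basis_matrix_values(t, params: PopulationParams, delta: float,
                        duration: float, step: float = GRID_STEP_MIN) -> np.ndarray:
    """All J basis components at times ``t``: an ``len(t) x J`` array."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tmax = float(np.max(t)) - min(0.0, delta)
    tg, B = _grid_for(params.alpha, params.beta, params.rates, duration, tmax, step)
    return _eval_delayed_matrix(tg, B, params.rates, t, delta)


def evaluate_aif(t, pop: PopulationParams, indiv: IndividualParams,
                 duration: float, step: float = GRID_STEP_MIN) -> np.ndarray:
    """Model AIF ``C_P(t) = sum_j pi_j A_j(t | delta, theta)``.

    Linear in the mixing weights; nonnegative for nonnegative weights.
    """
    if indiv.J != pop.J:
        raise ValueError(f"dimension mismatch: {indiv.J} weights for {pop.J} components")
    A = basis_matrix_values(t, pop, indiv.delta, duration, step)
    return A @ np.asarray(indiv.pi, dtype=float)
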