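"""Reference AIF models: tri-exponential (TE) and convolved tri-exponential (CTE).

TE fits the curve in two pieces — a linear rise from the signal start to
its peak, then a sum of three decaying exponentials constrained to equal
the peak value at the peak time.  CTE instead convolves a unit-area boxcar
injection profile with a sum of three exponentials, which removes the need
to specify the start/peak time points but assumes a fixed injection
duration.  Both serve as comparison baselines for the population
projection model.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .aif_core import SamplingCurve

__all__ = ["TEParams", "CTEParams", "te_eval", "cte_eval", "te_fit", "cte_fit"]

_RATE_INITS = (10.0, 1.0, 0.01)   # 1/min, log-spaced fast/medium/slow
_RATE_BOUNDS = (1e-4, 100.0)


@dataclass(frozen=True)
class TEParams:
    """Piecewise tri-exponential AIF parameters."""

    t_start: float
    t_peak: float
    peak_value: float
    amplitudes: tuple[float, float, float]
    rates: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.t_start < self.t_peak:
            raise ValueError("t_start must precede t_peak")
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be positive")


@dataclass(frozen=True)
class CTEParams:
    """Convolved tri-exponential AIF parameters."""

    amplitudes: tuple[float, float, float]
    rates: tuple[float, float, float]
    duration: float

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")


def te_eval(params: TEParams, t) -> np.ndarray:
    """Evaluate the TE model: zero, linear rise, tri-exponential decay."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    rise = (t > params.t_start) & (t <= params.t_peak)
    out[rise] = params.peak_value * (t[rise] - params.t_start) \
        / (params.t_peak - params.t_start)
    decay = t > params.t_peak
    u = t[decay] - params.t_peak
    out[decay] = sum(a * np.exp(-b * u)
                     for a, b in zip(params.amplitudes, params.rates))
    return out


def cte_eval(params: CTEParams, t) -> np.ndarray:
    """Evaluate the CTE model: unit-area boxcar (x) sum of exponentials.

    Closed form; for each rate b the convolution of the boxcar of width D
    with ``a exp(-b t)`` is ``a (exp(-b max(t-D, 0)) - exp(-b t)) / (b D)``
    (computed via expm1 for numerical stability at small b*D).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    D = params.duration
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    acc = np.zeros_like(tp)
    for a, b in zip(params.amplitudes, params.rates):
        early = tp < D
        term = np.empty_like(tp)
        term[early] = -np.expm1(-b * tp[early]) / (b * D)
        te = tp[~early]
        term[~early] = np.exp(-b * te) * np.expm1(b * D) / (b * D)
        acc += a * term
    out[pos] = acc
    return out


def _locate_shape(curve: SamplingCurve) -> tuple[float, float, float, int]:
    """(t_start, t_peak, peak_value, peak_index) from the samples.

    t_start is the last zero-concentration sample before the peak (or the
    first sample if the curve never reads zero); t_peak is the argmax.
    """
    z = curve.concentrations
    ip = int(np.argmax(z))
    if ip == 0 or ip == curve.m - 1:
        raise ValueError(f"{curve.subject_id}: peak at the boundary of the "
                         "time range; degenerate shape for TE/CTE fitting")
    zeros = np.flatnonzero(z[:ip] <= 0)
    t_start = curve.times[zeros[-1]] if zeros.size else curve.times[0]
    return float(t_start), float(curve.times[ip]), float(z[ip]), ip


def te_fit(curve: SamplingCurve) -> tuple[TEParams, np.ndarray]:
    """Fit the TE model; returns ``(params, fitted_values)``.

    The pre-peak rise is the line through (t_start, 0) and (t_peak, peak);
    the post-peak decay is fitted by bounded nonlinear least squares with
    the continuity constraint sum(a_i) = peak enforced through a stick-
    breaking parametrization of the amplitudes.
    """
    t_start, t_peak, peak, ip = _locate_shape(curve)
    t_post = curve.times[ip:] - t_peak
    z_post = curve.concentrations[ip:]
    w_post = np.sqrt(curve.weights[ip:])

    def unpack(x):
        f1, f2 = x[0], x[1]
        a1 = peak * f1
        a2 = peak * (1.0 - f1) * f2
        a3 = peak - a1 - a2
        return (a1, a2, a3), (x[2], x[3], x[4])

    def residuals(x):
        amps, rates = unpack(x)
        model = sum(a * np.exp(-b * t_post) for a, b in zip(amps, rates))
        return w_post * (z_post - model)

    x0 = [0.6, 0.6, *_RATE_INITS]
    lo = [0.0, 0.0, _RATE_BOUNDS[0], _RATE_BOUNDS[0], _RATE_BOUNDS[0]]
    hi = [1.0, 1.0, _RATE_BOUNDS[1], _RATE_BOUNDS[1], _RATE_BOUNDS[1]]
    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                 ftol=1e-12, xtol=1e-12, max_nfev=2000)
    amps, rates = unpack(sol.x)
    params = TEParams(t_start=t_start, t_peak=t_peak, peak_value=peak,
                      amplitudes=tuple(amps), rates=tuple(rates))
    return params, te_eval(params, curve.times)


def cte_fit(curve: SamplingCurve) -> tuple[CTEParams, np.ndarray]:
    """Fit the CTE model by bounded nonlinear least squares.

    Amplitudes are nonnegative; rates start from a log-spaced ladder.
    Deterministic given the data (fixed initialization and bounds).
    """
    D = curve.injection_duration
    peak = float(curve.concentrations.max())
    sw = np.sqrt(curve.weights)

    def residuals(x):
        params = CTEParams(amplitudes=tuple(x[:3]), rates=tuple(x[3:]), duration=D)
        return sw * (curve.concentrations - cte_eval(params, curve.times))

    scale = max(peak, 1e-12)
    x0 = [scale, 0.5 * scale, 0.1 * scale, *_RATE_INITS]
    lo = [0.0, 0.0, 0.0, _RATE_BOUNDS[0], _RATE_BOUNDS[0], _RATE_BOUNDS[0]]
    hi = [np.inf, np.inf, np.inf, _RATE_BOUNDS[1], _RATE_BOUNDS[1], _RATE_BOUNDS[1]]
    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                 ftol=1e-12, xtol=1e-12, max_nfev=2000)
    params = CTEParams(amplitudes=tuple(sol.x[:3]), rates=tuple(sol.x[3:]),
                       duration=D)
    return params, cte_eval(params, curve.times)
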