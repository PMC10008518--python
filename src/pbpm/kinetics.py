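"""One- and two-tissue compartment kinetic models driven by an AIF.

The tissue tracer concentration is governed by

    dC1/dt = K1 Cp(t) - (k2 + k3) C1(t) + k4 C2(t)
    dC2/dt = k3 C1(t) - k4 C2(t)

(1C model: k3 = k4 = 0), with the measured signal modeled as

    C_model(t) = (1 - VB) (C1(t) + C2(t)) + VB * Cp(t - delay),

where VB is the fractional blood volume in the tissue signal.  The linear
system is solved analytically: its impulse response is a sum of
exponentials (eigen-decomposition of the 2x2 rate matrix) convolved with
the input on a fine uniform grid using an exact exponential-kernel update.

Macro-parameters derived from the micro rates:
net influx Ki = K1 k3 / (k2 + k3), distribution volume VD = Ki / k3, and
non-displaceable volume Vnd = K1 / k2 (for the 1C model VD = Vnd = K1/k2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .aif_core import GRID_STEP_MIN, _exp_kernel_convolve

__all__ = ["CompartmentParams", "TissueCurve", "solve_compartments",
           "derive_macro", "fit_tac"]


@dataclass(frozen=True)
class CompartmentParams:
    """Compartment-model micro parameters.

    K1 in mL·cm^-3·min^-1; k2, k3, k4 in min^-1; VB (unitless fraction of
    blood in the tissue signal) in [0, 1]; delay in minutes.
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    VB: float = 0.0
    delay: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")
        if not 0.0 <= self.VB <= 1.0:
            raise ValueError(f"VB must be in [0, 1], got {self.VB}")


@dataclass
class TissueCurve:
    """Tissue time-activity curve: frame times (min) and activity values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tissue values must be finite")


def _as_input_function(aif):
    """Accept a callable Cp(t) or a (times, values) curve; return a callable."""
    if callable(aif):
        return aif
    if isinstance(aif, TissueCurve):
        t, v = aif.times, aif.values
    else:
        t, v = (np.asarray(a, dtype=float) for a in aif)
    return lambda x: np.interp(x, t, v, left=0.0)


def _decay_convolve(values: np.ndarray, rate: float, step: float) -> np.ndarray:
    """``int_0^t exp(-rate (t-s)) f(s) ds`` on a uniform grid."""
    if rate * step > 1e-12:
        return _exp_kernel_convolve(values, rate, step) / rate
    # rate -> 0: plain running integral
    return integrate.cumulative_trapezoid(values, dx=step, initial=0.0)


def solve_compartments(aif, params: CompartmentParams, times,
                       step: float = GRID_STEP_MIN,
                       return_components: bool = False):
    """Forward-evaluate the compartment model at the requested frame times.

    ``aif`` is the plasma input Cp, as a callable or a ``(times, values)``
    pair (interpolated linearly, zero before the first sample).  The state
    equations are solved through the eigen-decomposition of the rate
    matrix, each exponential mode convolved with the delayed input on a
    fine grid; ``k2 + k3 = 0`` degenerates gracefully to pure accumulation.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    cp = _as_input_function(aif)
    tmax = float(times.max())
    n = int(math.ceil(tmax / step)) + 1
    tg = np.arange(n + 1) * step
    cp_shifted = cp(tg - params.delay)

    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    if K1 == 0.0:
        C1g = np.zeros_like(tg)
        C2g = np.zeros_like(tg)
    elif k3 == 0.0 and k4 == 0.0:
        # one-tissue closed form: C1 = K1 e^{-k2 t} (x) Cp
        C1g = K1 * _decay_convolve(cp_shifted, k2, step)
        C2g = np.zeros_like(tg)
    else:
        M = np.array([[-(k2 + k3), k4], [k3, -k4]], dtype=float)
        lam, V = np.linalg.eig(M)
        if abs(lam[0] - lam[1]) < 1e-12 * max(1.0, abs(lam[0])):
            # degenerate eigenvalues: split them infinitesimally
            M[1, 1] -= 1e-9 * max(1.0, k2 + k3 + k4)
            lam, V = np.linalg.eig(M)
        coeff = np.linalg.solve(V, np.array([K1, 0.0]))
        modes = [_decay_convolve(cp_shifted, float(-lam[i]), step) for i in range(2)]
        C1g = (V[0, 0] * coeff[0]) * modes[0] + (V[0, 1] * coeff[1]) * modes[1]
        C2g = (V[1, 0] * coeff[0]) * modes[0] + (V[1, 1] * coeff[1]) * modes[1]
        C1g, C2g = C1g.real, C2g.real

    model_g = (1.0 - params.VB) * (C1g + C2g) + params.VB * cp_shifted
    values = np.interp(times, tg, model_g)
    curve = TissueCurve(times=times, values=values)
    if return_components:
        return curve, np.interp(times, tg, C1g), np.interp(times, tg, C2g)
    return curve


def derive_macro(params: CompartmentParams) -> dict:
    """Macro-parameters; quantities with a zero denominator come back NaN
    (flagged as undefined) rather than raising.
    """
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    out: dict[str, float] = {}
    out["Ki"] = K1 * k3 / (k2 + k3) if (k2 + k3) > 0 else (0.0 if k3 == 0 else np.nan)
    out["VD"] = out["Ki"] / k3 if k3 > 0 else np.nan
    out["Vnd"] = K1 / k2 if k2 > 0 else np.nan
    is_1c = (k3 == 0 and k4 == 0)
    if is_1c:
        out["VD"] = out["Vnd"]   # metabolically inert tracer: VD == Vnd
    out["Vt"] = K1 / k2 * (1.0 + k3 / k4) if (k2 > 0 and k4 > 0) else np.nan
    return out


def fit_tac(tac: TissueCurve, aif, model: str = "2c",
            init: CompartmentParams | None = None,
            bounds: dict | None = None,
            weights: np.ndarray | None = None,
            delay: float = 0.0,
            step: float = GRID_STEP_MIN):
    """Weighted nonlinear least squares fit of the compartment model.

    ``model='1c'`` fits (K1, k2, VB); ``model='2c'`` fits (K1, k2, k3, VB)
    with k4 fixed at zero.  The delay is held constant.  Returns
    ``(CompartmentParams, diagnostics_dict)``; non-convergence is flagged
    in the diagnostics, not raised.
    """
    if model not in ("1c", "2c"):
        raise ValueError(f"model must be '1c' or '2c', got {model!r}")
    two_c = model == "2c"
    w = np.ones(tac.times.size) if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)
    cp = _as_input_function(aif)

    if init is None:
        init = CompartmentParams(K1=0.1, k2=0.5, k3=0.05 if two_c else 0.0,
                                 VB=0.05, delay=delay)
    x0 = [init.K1, init.k2] + ([init.k3] if two_c else []) + [init.VB]
    b = bounds or {}
    lo = [b.get("K1", (1e-6, 10.0))[0], b.get("k2", (1e-6, 10.0))[0]] \
        + ([b.get("k3", (0.0, 5.0))[0]] if two_c else []) + [b.get("VB", (0.0, 1.0))[0]]
    hi = [b.get("K1", (1e-6, 10.0))[1], b.get("k2", (1e-6, 10.0))[1]] \
        + ([b.get("k3", (0.0, 5.0))[1]] if two_c else []) + [b.get("VB", (0.0, 1.0))[1]]

    def unpack(x) -> CompartmentParams:
        if two_c:
            return CompartmentParams(K1=x[0], k2=x[1], k3=x[2], k4=0.0,
                                     VB=x[3], delay=delay)
        return CompartmentParams(K1=x[0], k2=x[1], VB=x[2], delay=delay)

    def residuals(x):
        curve = solve_compartments(cp, unpack(x), tac.times, step=step)
        return sw * (tac.values - curve.values)

    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                 ftol=1e-10, xtol=1e-10, max_nfev=400)
    params = unpack(sol.x)
    diagnostics = {
        "converged": bool(sol.status > 0),
        "wrss": float(2.0 * sol.cost),
        "n_evaluations": int(sol.nfev),
        "message": sol.message,
    }
    return params, diagnostics
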