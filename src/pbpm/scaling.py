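"""Physiological scale-factor regression for normalized AIF curves.

AIF estimates obtained from normalized (unit-scale) data must be rescaled
to absolute activity-concentration units before kinetic analysis.  The
scale factor ``S`` is modeled log-linearly from routine, non-invasive
covariates:

    log(S) = b0 + b1 * X_ID + b2 * X_BV + b3 * pi_tail + noise,

where ``X_ID`` is the injected dose (mCi), ``X_BV`` the total blood volume
(litres, estimated from weight/height/sex) and ``pi_tail`` the fitted
weight of the slowest mixture component (the AIF tail height).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScaleModel", "estimate_blood_volume", "fit_scale_model", "predict_scale"]

COVARIATE_NAMES = ("injection_dose_mCi", "blood_volume_L", "pi_tail")

# Nadler (1962) total-blood-volume regression constants:
# height term (L per m^3), weight term (L per kg), intercept (L)
_NADLER = {
    "male": (0.3669, 0.03219, 0.6041),
    "female": (0.3561, 0.03308, 0.1833),
}


@dataclass
class ScaleModel:
    """Fitted log-linear scale model with training diagnostics."""

    coefficients: np.ndarray          # (b0, b1, b2, b3)
    covariate_names: tuple[str, ...] = COVARIATE_NAMES
    r_squared: float = np.nan
    residual_sd: float = np.nan
    n_train: int = 0


def estimate_blood_volume(weight_kg: float, height_cm: float, gender: str) -> float:
    """Total blood volume (litres) from the sex-specific Nadler formula.

    ``BV = c_h * height_m^3 + c_w * weight_kg + c_0`` with sex-specific
    constants.  ``gender`` must be 'male'/'m' or 'female'/'f'; there is no
    default because the formula is sex-specific.
    """
    if not (weight_kg > 0 and height_cm > 0):
        raise ValueError("weight and height must be positive")
    key = {"m": "male", "male": "male", "f": "female", "female": "female"}.get(
        str(gender).strip().lower())
    if key is None:
        raise ValueError(f"gender must be male/female, got {gender!r}")
    ch, cw, c0 = _NADLER[key]
    h_m = height_cm / 100.0
    return ch * h_m ** 3 + cw * weight_kg + c0


def fit_scale_model(training: np.ndarray) -> ScaleModel:
    """Ordinary least squares of log(S) on (X_ID, X_BV, pi_tail) + intercept.

    ``training`` is an (n, 4) array of rows ``(S, X_ID, X_BV, pi_tail)``
    with ``S > 0`` and ``n >= 5``.  Raises on a rank-deficient design,
    reporting its condition number.
    """
    T = np.atleast_2d(np.asarray(training, dtype=float))
    if T.shape[1] != 4:
        raise ValueError("training rows must be (S, X_ID, X_BV, pi_tail)")
    if T.shape[0] < 5:
        raise ValueError(f"need at least 5 training rows, got {T.shape[0]}")
    S = T[:, 0]
    if np.any(S <= 0):
        raise ValueError("scale factors must be positive")
    y = np.log(S)
    X = np.column_stack([np.ones(T.shape[0]), T[:, 1:]])
    cond = np.linalg.cond(X)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"collinear covariates: design rank {rank} < {X.shape[1]} "
            f"(condition number {cond:.3g})")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    dof = max(T.shape[0] - X.shape[1], 1)
    return ScaleModel(coefficients=beta, r_squared=r2,
                      residual_sd=float(np.sqrt(ss_res / dof)),
                      n_train=T.shape[0])


def predict_scale(model: ScaleModel, covariates: dict,
                  curve: np.ndarray | None = None):
    """Predicted scale ``S = exp(b0 + b1 X_ID + b2 X_BV + b3 pi_tail)``.

    ``covariates`` must provide every name in ``model.covariate_names``.
    When a normalized AIF ``curve`` is given, returns ``(S, S * curve)``;
    otherwise just ``S``.  Always positive (log link).
    """
    x = [1.0]
    for name in model.covariate_names:
        if name not in covariates:
            raise KeyError(f"missing covariate {name!r}")
        x.append(float(covariates[name]))
    S = float(np.exp(np.asarray(x) @ model.coefficients))
    if curve is None:
        return S
    return S, S * np.asarray(curve, dtype=float)
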