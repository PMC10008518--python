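"""Tracer presets: component counts, bounds, sampling frames, injection protocols.

Starting values and bounds for the population parameters come from
physiologic reasoning about tracer transit (injection-to-heart travel of a
fraction of a minute; AIF tails decaying over seconds to tens of minutes
depending on tracer metabolism) rather than from any single dataset; users
fitting their own cohorts should review them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TracerPreset", "TRACER_PRESETS", "get_preset"]


# median clinical sampling frames (minutes)
FDG_FRAME = (0, 0.25, 0.5, 0.75, 1, 1.5, 2, 2.5, 3, 4, 5, 6, 7, 10, 13, 15,
             20, 25, 30, 35, 40, 50, 60, 70, 80, 90)
H2O_FRAME = (0, 0.067, 0.13, 0.20, 0.27, 0.33, 0.40, 0.47, 0.53, 0.60, 0.67,
             0.73, 0.80, 0.87, 0.93, 1.08, 1.27, 1.42, 1.58, 1.75, 1.92, 2.25,
             2.58, 2.92, 3.25, 3.58, 3.92, 4.25, 4.58, 4.92)
FLT_FRAME = (0, 0.25, 0.5, 0.75, 1.00, 1.25, 1.5, 1.75, 2, 2.5, 3, 4, 5, 6, 7,
             8, 10, 15, 20, 30, 40, 50, 60, 90, 110)


@dataclass(frozen=True)
class TracerPreset:
    """Default modeling choices for one PET tracer."""

    name: str
    J: int                                   # mixture components
    injection_duration: float                # minutes
    frame: tuple[float, ...]                 # sampling times, minutes
    alpha0: float = 3.0
    beta0: float = 9.0                       # 1/min; travel-time mean alpha/beta ~ 20 s
    alpha_bounds: tuple[float, float] = (0.5, 20.0)
    beta_bounds: tuple[float, float] = (0.1, 60.0)
    phi_bounds: tuple[float, float] = (1e-3, 20.0)
    j_candidates: tuple[int, ...] = (2, 3, 4)

    def phi0(self) -> np.ndarray:
        """Log-spaced initial exponential rates, fastest first."""
        return np.geomspace(8.0, 0.02 if self.J > 2 else 0.3, self.J)

    def theta0(self) -> np.ndarray:
        return np.concatenate([[self.alpha0, self.beta0], self.phi0()])

    def theta_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.concatenate([[self.alpha_bounds[0], self.beta_bounds[0]],
                             np.full(self.J, self.phi_bounds[0])])
        hi = np.concatenate([[self.alpha_bounds[1], self.beta_bounds[1]],
                             np.full(self.J, self.phi_bounds[1])])
        return lo, hi


TRACER_PRESETS = {
    # FDG participates in metabolism; three components capture peak,
    # redistribution and slow tail.  1 min programmed infusion typical.
    "fdg": TracerPreset(name="fdg", J=3, injection_duration=1.0, frame=FDG_FRAME,
                        j_candidates=(2, 3, 4)),
    # 15O-water is metabolically inert and its studies are short (5 min);
    # two components suffice.  Manual bolus ~5 s.
    "h2o": TracerPreset(name="h2o", J=2, injection_duration=5.0 / 60.0, frame=H2O_FRAME,
                        j_candidates=(1, 2, 3)),
    # FLT behaves like FDG for input-function purposes.
    "flt": TracerPreset(name="flt", J=3, injection_duration=1.0, frame=FLT_FRAME,
                        j_candidates=(2, 3, 4)),
}


def get_preset(name: str) -> TracerPreset:
    try:
        return TRACER_PRESETS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown tracer preset {name!r}; "
                       f"available: {sorted(TRACER_PRESETS)}") from None
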