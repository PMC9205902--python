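"""Steady-state Kalman gain from planning and measurement variabilities.

For a random-walk state disturbed with planning variance ``sigma_x^2`` and
observed with measurement variance ``sigma_u^2``, the steady-state variance
of the optimal state estimate is

    sigma_{X+}^2 = (-sigma_x^2 + sqrt(sigma_x^4 + 4 sigma_x^2 sigma_u^2)) / 2

and the steady-state Kalman gain, i.e. the optimal weight given to the
experienced error, is

    K = (sigma_{X+}^2 + sigma_x^2) / (sigma_{X+}^2 + sigma_u^2 + sigma_x^2).

High planning variability relative to measurement variability pushes K
toward 1 (trust the error, correct fast); the reverse pushes K toward 0.
Inputs are variances (deg^2), not standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class SteadyStateGain:
    sigma_Xplus2: float
    K: float


def steady_state_variance(planning_var: float, measurement_var: float) -> float:
    """Steady-state estimate variance sigma_{X+}^2 (deg^2)."""
    vx = float(planning_var)
    vu = float(measurement_var)
    if vx < 0 or vu < 0:
        raise ValueError("variances must be >= 0")
    if vx == 0.0:
        return 0.0
    # rationalised form of (-vx + sqrt(vx^2 + 4 vx vu)) / 2: avoids the
    # catastrophic cancellation of the textbook expression when vu << vx
    return 2.0 * vx * vu / (vx + math.sqrt(vx * vx + 4.0 * vx * vu))


def steady_state_kalman_gain(planning_var: float, measurement_var: float) -> float:
    """Steady-state Kalman gain K in [0, 1]."""
    vx = float(planning_var)
    vu = float(measurement_var)
    if vx < 0 or vu < 0:
        raise ValueError("variances must be >= 0")
    if vx == 0 and vu == 0:
        raise ValueError("Kalman gain undefined for zero planning and measurement variance")
    v_plus = steady_state_variance(vx, vu)
    gain = (v_plus + vx) / (v_plus + vu + vx)
    return min(1.0, max(0.0, gain))


def steady_state(planning_var: float, measurement_var: float) -> SteadyStateGain:
    return SteadyStateGain(sigma_Xplus2=steady_state_variance(planning_var, measurement_var),
                           K=steady_state_kalman_gain(planning_var, measurement_var))
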