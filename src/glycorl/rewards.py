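"""Glycemic reward and dosing penalty.

The reward drives the agent toward the 140-180 mg/dL glucose band recommended
after cardiac surgery. It is a continuous five-branch piecewise-linear function
of the glucose level x (mg/dL):

    r(x) = -1                for x < 70          (hypoglycemia floor)
         = 3x/175 - 2.2      for 70 <= x < 140   (linear rise to the plateau)
         = 0.2               for 140 <= x < 180  (target plateau)
         = -0.03x + 5.6      for 180 <= x < 220  (linear fall)
         = -1                for x >= 220        (severe-hyperglycemia floor)

A quadratic penalty 0.001 * dose^2 on the administered insulin dose discourages
large overcorrections; the shaped reward is r(glucose) minus that penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RewardParams",
    "glycemic_reward",
    "action_penalty",
    "shaped_reward",
]

# Physiologic plausibility gate: values outside this band are data errors,
# not extreme physiology, and are rejected rather than clipped.
GLUCOSE_MIN = 20.0
GLUCOSE_MAX = 600.0


@dataclass(frozen=True)
class RewardParams:
    """Parameters of the piecewise glycemic reward and the dose penalty.

    Defaults reproduce the published reward exactly; they are exposed so the
    reward block of a YAML run config can override them.
    """

    hypo_cut: float = 70.0
    plateau_low: float = 140.0
    plateau_high: float = 180.0
    hyper_floor_cut: float = 220.0
    plateau_reward: float = 0.2
    floor_reward: float = -1.0
    rise_slope: float = 3.0 / 175.0
    rise_intercept: float = -2.2
    fall_slope: float = -0.03
    fall_intercept: float = 5.6
    penalty_coeff: float = 0.001

    def __post_init__(self) -> None:
        if not (self.hypo_cut < self.plateau_low < self.plateau_high < self.hyper_floor_cut):
            raise ValueError("reward cut points must be strictly increasing")
        if self.penalty_coeff < 0:
            raise ValueError("penalty_coeff must be non-negative")


DEFAULT_REWARD_PARAMS = RewardParams()


def _check_glucose(glucose: np.ndarray) -> None:
    if not np.all(np.isfinite(glucose)):
        raise ValueError("glucose must be finite")
    if np.any(glucose <= 0):
        raise ValueError("glucose must be positive (mg/dL)")
    if np.any((glucose < GLUCOSE_MIN) | (glucose > GLUCOSE_MAX)):
        raise ValueError(
            f"glucose outside plausible range [{GLUCOSE_MIN}, {GLUCOSE_MAX}] mg/dL; "
            "treat as a data error upstream"
        )


def glycemic_reward(glucose, params: RewardParams = DEFAULT_REWARD_PARAMS):
    """Piecewise glycemic reward of a glucose level in mg/dL.

    Accepts a scalar or array; branch membership uses half-open intervals
    (70 <= x < 140, 140 <= x < 180, 180 <= x < 220). Continuous at every
    boundary by construction of the default slopes/intercepts.
    """
    x = np.asarray(glucose, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    _check_glucose(x)
    p = params
    r = np.empty_like(x)
    r[x < p.hypo_cut] = p.floor_reward
    m = (x >= p.hypo_cut) & (x < p.plateau_low)
    r[m] = p.rise_slope * x[m] + p.rise_intercept
    m = (x >= p.plateau_low) & (x < p.plateau_high)
    r[m] = p.plateau_reward
    m = (x >= p.plateau_high) & (x < p.hyper_floor_cut)
    r[m] = p.fall_slope * x[m] + p.fall_intercept
    r[x >= p.hyper_floor_cut] = p.floor_reward
    return float(r[0]) if scalar else r


def action_penalty(dose, params: RewardParams = DEFAULT_REWARD_PARAMS):
    """Quadratic penalty on an insulin dose (units/h): coeff * dose**2."""
    a = np.asarray(dose, dtype=float)
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    if not np.all(np.isfinite(a)):
        raise ValueError("dose must be finite")
    if np.any(a < 0):
        raise ValueError("dose must be non-negative")
    pen = params.penalty_coeff * a**2
    return float(pen[0]) if scalar else pen


def shaped_reward(glucose, dose, params: RewardParams = DEFAULT_REWARD_PARAMS):
    """Glycemic reward minus the dose penalty, elementwise."""
    return glycemic_reward(glucose, params) - action_penalty(dose, params)
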