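"""QALYs over a one-year horizon from EQ-5D utilities at baseline and 12 weeks.

The trial measured utilities only at baseline (u0) and 12 weeks (u12).  QALYs
are the area under the piecewise-linear utility path over 52 weeks, with the
path after week 12 governed by an effect-persistence scenario:

* ``carry_forward`` (base case): the 12-week utility persists to week 52 —
  QALY = (12/52) * (u0 + u12)/2 + (40/52) * u12
* ``linear_return``: the utility declines linearly back to baseline by week
  52 — QALY = (12/52) * (u0 + u12)/2 + (40/52) * (u12 + u0)/2
* ``immediate_return``: the utility snaps back to baseline at week 12 —
  QALY = (12/52) * (u0 + u12)/2 + (40/52) * u0

Each is exactly a weighted mean ``w0 * u0 + w12 * u12``; no discounting is
applied (one-year horizon).  When u12 > u0 the scenarios are ordered
carry_forward >= linear_return >= immediate_return.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

SCENARIOS = ("carry_forward", "linear_return", "immediate_return")

#: QALY = w0 * u0 + w12 * u12 per scenario (exact areas; 1 year = 52 weeks).
_WEIGHTS = {
    "carry_forward": (3 / 26, 23 / 26),
    "linear_return": (1 / 2, 1 / 2),
    "immediate_return": (23 / 26, 3 / 26),
}


class EffectivenessError(ValueError):
    """Invalid utility inputs."""


@dataclass(frozen=True)
class QALYResult:
    value: float
    scenario: str
    u0: float
    u12: float


@dataclass(frozen=True)
class ArmQALY:
    arm_label: str
    qaly: float
    standard_error: float
    scenario: str


@dataclass(frozen=True)
class ArmQALYs:
    """Per-arm QALYs plus differences against a reference arm."""

    scenario: str
    values: Mapping[str, ArmQALY]
    reference: str
    differences: Mapping[str, tuple[float, float]]  # arm -> (diff vs ref, se)


def scenario_weights(scenario: str) -> tuple[float, float]:
    """(w0, w12) such that QALY = w0*u0 + w12*u12 for the scenario."""
    try:
        return _WEIGHTS[scenario]
    except KeyError:
        raise EffectivenessError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}") from None


def qaly_auc(u0: float, u12: float, scenario: str = "carry_forward") -> QALYResult:
    """One-year QALY as the exact area under the scenario's utility path."""
    for name, u in (("u0", u0), ("u12", u12)):
        if not (np.isfinite(u) and 0 <= u <= 1):
            raise EffectivenessError(f"utility {name} must be in [0, 1], got {u}")
    w0, w12 = scenario_weights(scenario)
    return QALYResult(value=float(w0 * u0 + w12 * u12), scenario=scenario,
                      u0=float(u0), u12=float(u12))


def arm_qaly(utilities: Mapping[str, tuple[float, float, float, float]],
             scenario: str = "carry_forward", reference: str = "SCP") -> ArmQALYs:
    """Per-arm QALY (+ delta-method s.e.) and differences versus a reference.

    ``utilities`` maps arm -> (u0, u12, se_u0, se_u12); the standard error of
    the QALY is ``sqrt(w0^2 se0^2 + w12^2 se12^2)`` treating the baseline and
    adjusted 12-week estimates as independent.
    """
    if reference not in utilities:
        raise EffectivenessError(f"reference arm {reference!r} missing from utilities")
    w0, w12 = scenario_weights(scenario)
    values = {}
    for arm, (u0, u12, se0, se12) in utilities.items():
        res = qaly_auc(u0, u12, scenario)
        se = float(np.sqrt((w0 * se0) ** 2 + (w12 * se12) ** 2))
        values[arm] = ArmQALY(arm_label=arm, qaly=res.value,
                              standard_error=se, scenario=scenario)
    ref = values[reference]
    differences = {
        arm: (v.qaly - ref.qaly,
              float(np.sqrt(v.standard_error**2 + ref.standard_error**2)))
        for arm, v in values.items() if arm != reference
    }
    return ArmQALYs(scenario=scenario, values=values, reference=reference,
                    differences=differences)
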