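"""Decision-tree expected-cost model over service-use combinations.

During the year after randomization every participant falls into exactly one of
five service-use combinations: no services, physician only,
physician + outpatient, physician + inpatient, or all three sectors.  The
decision tree weights the cost of each branch (the sum of the mean sector costs
among users of those sectors) by the branch probability, giving the expected
one-year cost per participant for an arm:

    E[cost] = p_phys * C_p + p_phys_out * (C_p + C_o)
            + p_phys_inp * (C_p + C_i) + p_all * (C_p + C_o + C_i)

where C_p, C_o, C_i are the physician / outpatient / inpatient mean costs among
users.  The no-services branch contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The five service-use combinations, in tree order.
COMBOS = ("none", "phys_only", "phys_out", "phys_inp", "phys_out_inp")

#: Sectors with positive cost in each combination.
COMBO_SECTORS: Mapping[str, tuple[str, ...]] = {
    "none": (),
    "phys_only": ("physician",),
    "phys_out": ("physician", "outpatient"),
    "phys_inp": ("physician", "inpatient"),
    "phys_out_inp": ("physician", "outpatient", "inpatient"),
}

_SUM_TOL = 1e-9


class TreeError(ValueError):
    """Invalid decision-tree inputs."""


@dataclass(frozen=True)
class ServiceMix:
    """Probabilities over the five service-use combinations (must sum to 1)."""

    p_none: float
    p_phys: float
    p_phys_out: float
    p_phys_inp: float
    p_all: float

    def __post_init__(self):
        probs = self.as_array()
        if not np.all(np.isfinite(probs)):
            raise TreeError("service-mix probabilities must be finite")
        if np.any(probs < 0) or np.any(probs > 1):
            raise TreeError(f"service-mix probabilities outside [0, 1]: {probs}")
        if abs(probs.sum() - 1.0) > _SUM_TOL:
            raise TreeError(f"service-mix probabilities sum to {probs.sum()!r}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_none, self.p_phys, self.p_phys_out,
                         self.p_phys_inp, self.p_all], dtype=float)

    @classmethod
    def from_counts(cls, counts: Sequence[float]) -> "ServiceMix":
        """Build a mix from category counts (tree order); counts need not sum to 1."""
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (5,):
            raise TreeError("expected 5 category counts")
        if np.any(counts < 0):
            raise TreeError("category counts must be non-negative")
        total = counts.sum()
        if total <= 0:
            raise TreeError("category counts sum to zero")
        p = counts / total
        return cls(*p)

    @classmethod
    def from_probabilities(cls, probs: Sequence[float]) -> "ServiceMix":
        """Build a mix from probabilities, renormalizing tiny rounding slack.

        Printed percentages rarely sum to exactly 1; deviations up to 1% are
        renormalized, anything larger is rejected.
        """
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (5,):
            raise TreeError("expected 5 probabilities")
        total = probs.sum()
        if abs(total - 1.0) > 0.01:
            raise TreeError(f"probabilities sum to {total}, too far from 1")
        return cls(*(probs / total))


@dataclass(frozen=True)
class SectorMeans:
    """Mean one-year cost among users of each sector (2017 CAD)."""

    physician: float
    outpatient: float
    inpatient: float

    def __post_init__(self):
        for name in ("physician", "outpatient", "inpatient"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise TreeError(f"sector mean {name} must be finite and >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {"physician": self.physician, "outpatient": self.outpatient,
                "inpatient": self.inpatient}


@dataclass(frozen=True)
class ExpectedCost:
    """Decision-tree expected cost per participant with per-branch contributions."""

    arm_label: str
    total: float
    branch_contributions: tuple[float, float, float, float, float]


def branch_costs(means: SectorMeans) -> np.ndarray:
    """Cost of each branch: sum of the sector means present in the combination."""
    lookup = means.as_dict()
    return np.array([sum(lookup[s] for s in COMBO_SECTORS[c]) for c in COMBOS])


def expected_cost(mix: ServiceMix, means: SectorMeans, arm_label: str = "") -> ExpectedCost:
    """Branch-probability-weighted expected one-year cost per participant."""
    contributions = mix.as_array() * branch_costs(means)
    return ExpectedCost(arm_label=arm_label, total=float(contributions.sum()),
                        branch_contributions=tuple(float(c) for c in contributions))


def _mix_from_combo_series(combos: pd.Series) -> ServiceMix:
    counts = combos.value_counts()
    return ServiceMix.from_counts([int(counts.get(c, 0)) for c in COMBOS])


def estimate_service_mix(cohort: pd.DataFrame, arm: str,
                         combo_column: str = "service_combo") -> ServiceMix:
    """Empirical service-mix probabilities for one arm of a classified cohort."""
    sub = cohort.loc[cohort["arm"] == arm, combo_column]
    if len(sub) == 0:
        raise TreeError(f"arm {arm!r} has no records")
    return _mix_from_combo_series(sub)


def pooled_service_mix(cohort: pd.DataFrame,
                       combo_column: str = "service_combo") -> ServiceMix:
    """Service mix pooled over all arms (the identical-mix sensitivity scenario)."""
    if len(cohort) == 0:
        raise TreeError("empty cohort")
    return _mix_from_combo_series(cohort[combo_column])


def arm_expected_costs(mixes: Mapping[str, ServiceMix],
                       means: Mapping[str, SectorMeans],
                       arms: Iterable[str] | None = None) -> dict[str, ExpectedCost]:
    """Run the tree for several arms at once."""
    arms = tuple(arms) if arms is not None else tuple(mixes)
    return {a: expected_cost(mixes[a], means[a], arm_label=a) for a in arms}
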