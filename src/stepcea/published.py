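"""Published summary statistics of the four-arm primary-care depression trial.

The patient-level administrative data behind the trial's economic evaluation are
not publicly deposited, but the published summary tables are, and they are both
the calibration targets for the synthetic cohort generator and the inputs for
"table-reproduction" mode, in which the decision-tree cost model, QALY
construction and probabilistic sensitivity analysis are run directly off the
printed numbers.

Four strategies were compared:

* ``SC``   -- standard care (screening results withheld),
* ``TAU``  -- treatment as usual (screening results shared with the physician),
* ``ICBT`` -- treatment as usual plus online cognitive behavioural therapy,
* ``SCP``  -- a protocolized stepped-care pathway.

All costs are 2017 Canadian dollars. ``"all"`` refers to every randomized
participant, ``"depressed"`` to the subgroup scoring above 10 on the PHQ-9 at
baseline.
"""

from __future__ import annotations

from types import MappingProxyType
from typing import Mapping

from .cost_tree import SectorMeans, ServiceMix

ARMS = ("SC", "TAU", "ICBT", "SCP")
POPULATIONS = ("all", "depressed")

# ---------------------------------------------------------------------------
# Service-use combinations during the year after randomization
# (counts of participants: no services, physician only, physician+outpatient,
#  physician+inpatient, physician+outpatient+inpatient).  Cells the trial
#  reported as "na" are zero counts.
# ---------------------------------------------------------------------------

SERVICE_COUNTS: Mapping[str, Mapping[str, tuple[int, int, int, int, int]]] = MappingProxyType({
    "all": MappingProxyType({
        "SC":   (4, 179, 176, 3, 53),
        "TAU":  (8, 160, 160, 2, 69),
        "ICBT": (4, 188, 164, 7, 59),
        "SCP":  (3, 75, 88, 0, 17),
        "All":  (19, 602, 588, 12, 198),
    }),
    "depressed": MappingProxyType({
        "SC":   (0, 21, 28, 0, 7),
        "TAU":  (2, 21, 35, 0, 8),
        "ICBT": (0, 22, 23, 0, 5),
        "SCP":  (0, 12, 18, 0, 4),
        "All":  (2, 76, 104, 0, 24),
    }),
})


def service_mix(population: str, arm: str) -> ServiceMix:
    """Service-mix probabilities for one arm, computed from the printed counts."""
    return ServiceMix.from_counts(SERVICE_COUNTS[population][arm])


# ---------------------------------------------------------------------------
# Sample description: demographics and outcome scores.
# Each entry: n, (age mean, sd), female fraction,
#             (PHQ-9 baseline mean, sd), (PHQ-9 12-week mean, sd),
#             (EQ-5D baseline mean, sd), (EQ-5D 12-week mean, sd).
# ---------------------------------------------------------------------------

class OutcomeSummary:
    """Per-arm demographic and outcome summary (one population panel row)."""

    __slots__ = ("n", "age", "female", "phq9_baseline", "phq9_12wk",
                 "eq5d_baseline", "eq5d_12wk")

    def __init__(self, n, age, female, phq9_baseline, phq9_12wk,
                 eq5d_baseline, eq5d_12wk):
        self.n = n
        self.age = age
        self.female = female
        self.phq9_baseline = phq9_baseline
        self.phq9_12wk = phq9_12wk
        self.eq5d_baseline = eq5d_baseline
        self.eq5d_12wk = eq5d_12wk

    def __repr__(self):  # pragma: no cover - debugging aid
        return (f"OutcomeSummary(n={self.n}, phq9_baseline={self.phq9_baseline}, "
                f"eq5d_baseline={self.eq5d_baseline})")


OUTCOMES: Mapping[str, Mapping[str, OutcomeSummary]] = MappingProxyType({
    "all": MappingProxyType({
        "SC":   OutcomeSummary(412, (46.9, 17.1), 0.75, (4.55, 4.95), (3.85, 2.94), (0.86, 0.11), (0.88, 0.06)),
        "TAU":  OutcomeSummary(397, (45.5, 16.3), 0.78, (4.98, 5.19), (4.12, 3.09), (0.84, 0.14), (0.87, 0.08)),
        "ICBT": OutcomeSummary(415, (46.6, 16.8), 0.70, (4.20, 4.61), (3.65, 2.74), (0.86, 0.12), (0.88, 0.07)),
        "SCP":  OutcomeSummary(183, (52.3, 17.6), 0.61, (4.86, 5.54), (4.04, 3.29), (0.86, 0.13), (0.88, 0.08)),
        "All":  OutcomeSummary(1407, (47.1, 17.0), 0.73, (4.61, 5.01), (3.89, 2.98), (0.86, 0.12), (0.88, 0.07)),
    }),
    "depressed": MappingProxyType({
        "SC":   OutcomeSummary(56, (44.7, 16.3), 0.80, (14.73, 4.17), (9.90, 2.48), (0.68, 0.18), (0.78, 0.10)),
        "TAU":  OutcomeSummary(66, (44.8, 14.2), 0.70, (14.83, 3.91), (9.94, 2.31), (0.63, 0.20), (0.74, 0.12)),
        "ICBT": OutcomeSummary(50, (42.2, 13.8), 0.70, (14.28, 3.76), (9.64, 2.24), (0.67, 0.22), (0.77, 0.13)),
        "SCP":  OutcomeSummary(34, (49.0, 16.4), 0.74, (14.85, 3.84), (9.98, 2.28), (0.68, 0.21), (0.78, 0.12)),
        "All":  OutcomeSummary(206, (44.8, 15.1), 0.74, (14.67, 3.91), (9.86, 2.32), (0.66, 0.20), (0.76, 0.12)),
    }),
})

# ---------------------------------------------------------------------------
# Sector costs among service users for the year after randomization.
# Each entry: (n users, mean, sd).
# Note: the depressed-subgroup SCP physician sd is printed as 648 in the source
# table, which is inconsistent with its mean (633.6) and range [234, 901]; it is
# reproduced as printed and not used by the generator defaults.
# ---------------------------------------------------------------------------

SECTOR_COSTS: Mapping[str, Mapping[str, Mapping[str, tuple[int, float, float]]]] = MappingProxyType({
    "all": MappingProxyType({
        "SC":   MappingProxyType({"physician": (395, 683.75, 241.0), "outpatient": (198, 1036.58, 386.0), "inpatient": (56, 8472.98, 4916.0)}),
        "TAU":  MappingProxyType({"physician": (375, 758.17, 269.0), "outpatient": (200, 1002.32, 392.0), "inpatient": (70, 8158.80, 5819.0)}),
        "ICBT": MappingProxyType({"physician": (394, 667.49, 214.0), "outpatient": (193, 945.89, 340.0), "inpatient": (66, 8477.81, 5340.0)}),
        "SCP":  MappingProxyType({"physician": (172, 559.00, 207.0), "outpatient": (90, 1144.49, 611.0), "inpatient": (17, 10670.27, 3994.0)}),
        "All":  MappingProxyType({"physician": (1336, 683.78, 245.0), "outpatient": (681, 1015.07, 416.0), "inpatient": (209, 8548.00, 5309.0)}),
    }),
    "depressed": MappingProxyType({
        "SC":   MappingProxyType({"physician": (52, 802.56, 285.0), "outpatient": (33, 1256.53, 498.0), "inpatient": (7, 11953.99, 4257.0)}),
        "TAU":  MappingProxyType({"physician": (60, 996.41, 326.0), "outpatient": (38, 1188.60, 428.0), "inpatient": (7, 14771.99, 6465.0)}),
        "ICBT": MappingProxyType({"physician": (48, 787.08, 216.0), "outpatient": (24, 1101.80, 420.0), "inpatient": (5, 9357.69, 2698.0)}),
        "SCP":  MappingProxyType({"physician": (31, 633.60, 648.0), "outpatient": (21, 1800.39, 648.0), "inpatient": (4, 10820.99, 2660.0)}),
        "All":  MappingProxyType({"physician": (191, 832.14, 298.0), "outpatient": (116, 1300.72, 543.0), "inpatient": (23, 12050.19, 4787.0)}),
    }),
})


def sector_user_means(population: str, arm: str) -> SectorMeans:
    """Mean one-year sector costs among users of each sector (printed values)."""
    row = SECTOR_COSTS[population][arm]
    return SectorMeans(physician=row["physician"][1],
                       outpatient=row["outpatient"][1],
                       inpatient=row["inpatient"][1])


# ---------------------------------------------------------------------------
# Pre-randomization (12-week prior) sector costs by depression status:
# (n, mean, sd) among users; pooled values derived below are the generator's
# pre-period defaults (the trial did not print pre-period costs by arm).
# ---------------------------------------------------------------------------

PRE_PERIOD_COSTS_BY_STATUS: Mapping[str, Mapping[str, tuple[int, float, float]]] = MappingProxyType({
    "physician":  MappingProxyType({"depressed": (147, 282.32, 52.0), "non_depressed": (734, 228.04, 35.0)}),
    "outpatient": MappingProxyType({"depressed": (57, 727.89, 195.0), "non_depressed": (245, 651.66, 105.0)}),
    "inpatient":  MappingProxyType({"depressed": (10, 10010.70, 2812.0), "non_depressed": (51, 8517.04, 3913.0)}),
})


def pooled_pre_period_costs() -> tuple[SectorMeans, SectorMeans]:
    """Pool the by-status pre-randomization user costs into (means, sds).

    Pooling combines the two status groups by user counts; the pooled variance
    includes the between-group mean spread (law of total variance).
    """
    means = {}
    sds = {}
    for sector, rows in PRE_PERIOD_COSTS_BY_STATUS.items():
        n1, m1, s1 = rows["depressed"]
        n2, m2, s2 = rows["non_depressed"]
        n = n1 + n2
        m = (n1 * m1 + n2 * m2) / n
        ex2 = (n1 * (s1**2 + m1**2) + n2 * (s2**2 + m2**2)) / n
        means[sector] = m
        sds[sector] = (ex2 - m * m) ** 0.5
    return (SectorMeans(**means), SectorMeans(**sds))


# ---------------------------------------------------------------------------
# Cost-effectiveness results: per-arm decision-tree sector means, totals and
# QALYs with the spreads used in the probabilistic sensitivity analysis.
# Each entry: sector -> (mean, sd); "total" and "qaly" likewise.
# ---------------------------------------------------------------------------

CEA_RESULTS: Mapping[str, Mapping[str, Mapping[str, tuple[float, float]]]] = MappingProxyType({
    "all": MappingProxyType({
        "SC":   MappingProxyType({"physician": (678.0, 239.0), "outpatient": (572.0, 212.0), "inpatient": (1096.0, 630.0), "total": (2346.0, 655.0), "qaly": (0.881, 0.003)}),
        "TAU":  MappingProxyType({"physician": (744.0, 263.0), "outpatient": (575.0, 228.0), "inpatient": (1421.0, 1006.0), "total": (2740.0, 968.0), "qaly": (0.870, 0.004)}),
        "ICBT": MappingProxyType({"physician": (661.0, 213.0), "outpatient": (490.0, 177.0), "inpatient": (1202.0, 758.0), "total": (2353.0, 767.0), "qaly": (0.881, 0.003)}),
        "SCP":  MappingProxyType({"physician": (548.0, 205.0), "outpatient": (653.0, 351.0), "inpatient": (990.0, 372.0), "total": (2191.0, 539.0), "qaly": (0.882, 0.005)}),
    }),
    "depressed": MappingProxyType({
        "SC":   MappingProxyType({"physician": (794.0, 281.0), "outpatient": (787.0, 314.0), "inpatient": (1497.0, 535.0), "total": (3078.0, 677.0), "qaly": (0.766, 0.014)}),
        "TAU":  MappingProxyType({"physician": (966.0, 316.0), "outpatient": (770.0, 278.0), "inpatient": (1779.0, 780.0), "total": (3516.0, 890.0), "qaly": (0.730, 0.014)}),
        "ICBT": MappingProxyType({"physician": (784.0, 217.0), "outpatient": (618.0, 234.0), "inpatient": (1119.0, 321.0), "total": (2522.0, 455.0), "qaly": (0.758, 0.017)}),
        "SCP":  MappingProxyType({"physician": (634.0, 210.0), "outpatient": (1163.0, 416.0), "inpatient": (1279.0, 315.0), "total": (3075.0, 565.0), "qaly": (0.767, 0.021)}),
    }),
})


def cea_arm_distributions(population: str = "all"):
    """PSA input distributions (total cost and QALY mean/sd) per arm.

    Returns a list of :class:`stepcea.psa.ArmDistribution` built from the
    published cost-effectiveness table, the parameterization used for the
    scatterplot and acceptability-curve reproduction.
    """
    from .psa import ArmDistribution  # local import to avoid a cycle

    dists = []
    for arm in ARMS:
        row = CEA_RESULTS[population][arm]
        dists.append(ArmDistribution(arm_label=arm,
                                     cost_mean=row["total"][0], cost_sd=row["total"][1],
                                     qaly_mean=row["qaly"][0], qaly_sd=row["qaly"][1]))
    return dists
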