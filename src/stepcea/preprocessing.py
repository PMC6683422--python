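"""Cleaning and structuring of patient-level data.

Covers the four pre-analysis steps: classifying each participant into one of
the five service-use combinations, boxplot (1.5 x IQR) trimming of physician
and outpatient costs per arm x period x sector, multiple imputation of missing
12-week outcomes by chained equations, and extraction of the depressed
subgroup (baseline PHQ-9 strictly greater than 10).

Trimming removes cost *observations*, not participants: a record whose
physician cost is an outlier still contributes its outpatient cost and its
outcome scores.  Inpatient costs are never trimmed (too few admissions to
distinguish outliers from genuine expensive stays); callers must not route
them through :func:`trim_outliers`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.imputation.mice import MICEData

from .cohort import OUTCOME_12WK_COLUMNS, PERIODS, SECTORS

logger = logging.getLogger(__name__)

PHQ9_DEPRESSED_THRESHOLD = 10  # strictly greater-than


class DataError(ValueError):
    """Invalid patient-level data."""


# ---------------------------------------------------------------------------
# Service-combination classification
# ---------------------------------------------------------------------------

def classify_service_combination(physician: float, outpatient: float,
                                 inpatient: float) -> str:
    """Service-use combination implied by the three sector costs.

    ``none`` iff all three costs are zero; otherwise the set of sectors with
    positive cost.  Patterns without a physician component (possible in
    external data, not produced by the tree) are mapped to the nearest
    combination containing their sectors and counted in the log.
    """
    for name, v in (("physician", physician), ("outpatient", outpatient),
                    ("inpatient", inpatient)):
        if v < 0 or not np.isfinite(v):
            raise DataError(f"negative or non-finite {name} cost: {v}")
    key = (physician > 0, outpatient > 0, inpatient > 0)
    mapping = {
        (False, False, False): "none",
        (True, False, False): "phys_only",
        (True, True, False): "phys_out",
        (True, False, True): "phys_inp",
        (True, True, True): "phys_out_inp",
        # no physician cost: nearest combination containing the used sectors
        (False, True, False): "phys_out",
        (False, False, True): "phys_inp",
        (False, True, True): "phys_out_inp",
    }
    return mapping[key]


def window_costs(cohort: pd.DataFrame, window: str = "year") -> pd.DataFrame:
    """Per-sector costs over a period window; ``year`` = post + late."""
    periods = {"year": ("post", "late")}.get(window, (window,))
    for p in periods:
        if p not in PERIODS:
            raise DataError(f"unknown period window {window!r}")
    out = {}
    for sector in SECTORS:
        cols = [f"cost_{sector}_{p}" for p in periods]
        out[sector] = cohort[cols].sum(axis=1, min_count=1)
    return pd.DataFrame(out, index=cohort.index)


def classify_cohort(cohort: pd.DataFrame, window: str = "year") -> pd.Series:
    """Vectorized combination classification over a window (default one year)."""
    costs = window_costs(cohort, window)
    if (costs.fillna(0) < 0).to_numpy().any():
        raise DataError("negative sector costs")
    phys = costs["physician"].to_numpy() > 0
    outp = costs["outpatient"].to_numpy() > 0
    inp = costs["inpatient"].to_numpy() > 0
    combo = np.where(~phys & ~outp & ~inp, "none",
             np.where(outp & inp, "phys_out_inp",
              np.where(outp, "phys_out",
               np.where(inp, "phys_inp", "phys_only"))))
    n_nophys = int((~phys & (outp | inp)).sum())
    if n_nophys:
        logger.warning("%d records use outpatient/inpatient services without "
                       "physician cost; mapped to nearest combination", n_nophys)
    return pd.Series(combo, index=cohort.index, name="service_combo")


# ---------------------------------------------------------------------------
# Boxplot trimming
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimReport:
    """Audit record of one trimming pass (fences computed on the input)."""

    arm_label: str
    period: str
    sector: str
    n_before: int
    n_removed: int
    lower_fence: float
    upper_fence: float
    quantile_method: str = "linear"  # numpy type-7: linear interpolation


def trim_outliers(costs, factor: float = 1.5, arm_label: str = "",
                  period: str = "", sector: str = "") -> tuple[np.ndarray, TrimReport]:
    """Keep values within [Q1 - factor*IQR, Q3 + factor*IQR] of the input.

    Quartiles use linear interpolation between order statistics (numpy's
    default, R type 7); the convention is recorded in the report so results
    are auditable.  Not idempotent in general: fences are recomputed on each
    call's input.
    """
    values = np.asarray(costs, dtype=float)
    if values.size == 0:
        raise DataError("cannot trim an empty cost vector")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise DataError("cost vector must be finite and non-negative")
    if factor <= 0:
        raise DataError(f"trim factor must be > 0, got {factor}")
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    keep = (values >= lo) & (values <= hi)
    report = TrimReport(arm_label=arm_label, period=period, sector=sector,
                        n_before=int(values.size), n_removed=int((~keep).sum()),
                        lower_fence=float(lo), upper_fence=float(hi))
    return values[keep], report


def trim_cohort(cohort: pd.DataFrame, factor: float = 1.5,
                sectors: Sequence[str] = ("physician", "outpatient"),
                periods: Sequence[str] = PERIODS) -> tuple[pd.DataFrame, list[TrimReport]]:
    """Trim cost cells per arm x period x sector among users (positive costs).

    Trimmed cells become NaN (observation excluded) so the record stays in the
    analysis for its other sectors.  Inpatient costs are deliberately not in
    the default sector list and are rejected if requested.
    """
    if "inpatient" in sectors:
        raise DataError("inpatient costs are never trimmed (caller contract)")
    out = cohort.copy()
    reports: list[TrimReport] = []
    for arm in out["arm"].unique():
        arm_mask = out["arm"] == arm
        for sector in sectors:
            for period in periods:
                col = f"cost_{sector}_{period}"
                users = arm_mask & (out[col] > 0)
                vals = out.loc[users, col].to_numpy(float)
                if vals.size == 0:
                    continue
                _, report = trim_outliers(vals, factor, arm_label=str(arm),
                                          period=period, sector=sector)
                drop = users & ((out[col] < report.lower_fence)
                                | (out[col] > report.upper_fence))
                out.loc[drop, col] = np.nan
                reports.append(report)
    return out, reports


def trim_reports_frame(reports: Iterable[TrimReport]) -> pd.DataFrame:
    """Trim reports as a flat table (the CSV audit artifact)."""
    return pd.DataFrame([r.__dict__ for r in reports])


# ---------------------------------------------------------------------------
# Multiple imputation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImputedSet:
    """m completed datasets; estimates computed per dataset are pooled by
    Rubin's rules (see :func:`stepcea.adjustment.rubin_pool`)."""

    m: int
    datasets: tuple[pd.DataFrame, ...]
    method: str = "mice-pmm"

    def __post_init__(self):
        if self.m < 1 or len(self.datasets) != self.m:
            raise DataError("ImputedSet requires m >= 1 datasets")


def impute_missing(cohort: pd.DataFrame, m: int = 20, seed: int = 0,
                   n_burn: int = 5) -> ImputedSet:
    """Multiple imputation of missing 12-week outcomes by chained equations.

    Uses predictive-mean-matching draws conditioning on arm, age, sex and the
    baseline scores (statsmodels MICE).  A fully observed cohort passes
    through unchanged (all m datasets identical).
    """
    if m < 1:
        raise DataError(f"m must be >= 1, got {m}")
    missing_cols = [c for c in OUTCOME_12WK_COLUMNS if cohort[c].isna().any()]
    for c in OUTCOME_12WK_COLUMNS:
        if len(cohort) and cohort[c].isna().all():
            raise DataError(f"{c} is 100% missing; cannot impute")
    baseline_cols = ["age", "phq9_baseline", "eq5d_baseline"]
    if cohort[baseline_cols].isna().any().any():
        raise DataError("missingness must be confined to 12-week outcomes")
    if not missing_cols:
        return ImputedSet(m=m, datasets=tuple(cohort.copy() for _ in range(m)),
                          method="complete-data passthrough")

    work = cohort[["age", "phq9_baseline", "eq5d_baseline"]].copy()
    work["female"] = (cohort["sex"] == "female").astype(float)
    arm_dummies = pd.get_dummies(cohort["arm"], prefix="arm", drop_first=True, dtype=float)
    work = pd.concat([work, arm_dummies], axis=1)
    for c in OUTCOME_12WK_COLUMNS:
        work[c] = cohort[c].astype(float)

    datasets = []
    seeds = np.random.SeedSequence(seed).generate_state(m) // 2
    for i in range(m):
        # statsmodels MICE draws from the global numpy RNG
        np.random.seed(int(seeds[i]))
        mice = MICEData(work.copy(), perturbation_method="gaussian", k_pmm=20)
        mice.update_all(n_burn)
        completed = cohort.copy()
        for c in missing_cols:
            completed[c] = mice.data[c].to_numpy()
        completed["phq9_12wk"] = completed["phq9_12wk"].clip(0, 27)
        completed["eq5d_12wk"] = completed["eq5d_12wk"].clip(0, 1)
        datasets.append(completed)
    return ImputedSet(m=m, datasets=tuple(datasets))


# ---------------------------------------------------------------------------
# Subgroup and descriptives
# ---------------------------------------------------------------------------

def subgroup_depressed(cohort: pd.DataFrame) -> pd.DataFrame:
    """Records with baseline PHQ-9 strictly greater than 10."""
    if cohort["phq9_baseline"].isna().any():
        raise DataError("phq9_baseline must be present for all records")
    return cohort[cohort["phq9_baseline"] > PHQ9_DEPRESSED_THRESHOLD].copy()


def _bootstrap_ci(values: np.ndarray, stat, n_boot: int, rng,
                  level: float = 0.95) -> tuple[float, float]:
    n = len(values)
    reps = np.array([stat(values[rng.integers(0, n, n)]) for _ in range(n_boot)])
    alpha = (1 - level) / 2
    return tuple(np.quantile(reps, [alpha, 1 - alpha]))


def descriptive_summary(cohort: pd.DataFrame, n_boot: int = 500,
                        seed: int = 0, include_pooled: bool = True) -> pd.DataFrame:
    """Per-arm outcome summary: means, sds, ranges, and baseline-to-12-week
    changes (PHQ-9 improvement positive, EQ-5D gain positive) with bootstrap
    percentile CIs on the changes.

    Arms with no records are omitted with a warning; single-record arms report
    sd 0 with a ``degenerate`` flag.
    """
    rng = np.random.default_rng(seed)
    arms = [a for a in cohort["arm"].unique()]
    groups = [(a, cohort[cohort["arm"] == a]) for a in arms]
    if include_pooled and len(cohort):
        groups.append(("All", cohort))
    rows = []
    for arm, g in groups:
        if len(g) == 0:
            logger.warning("arm %s has no records; omitted from summary", arm)
            continue
        row = {"arm": arm, "n": len(g), "degenerate": len(g) < 2}
        for var, sign in (("phq9", -1), ("eq5d", +1)):
            b = g[f"{var}_baseline"].to_numpy(float)
            f = g[f"{var}_12wk"].to_numpy(float)
            obs = ~np.isnan(f)
            row[f"{var}_baseline_mean"] = b.mean()
            row[f"{var}_baseline_sd"] = b.std(ddof=1) if len(g) > 1 else 0.0
            row[f"{var}_baseline_range"] = (b.min(), b.max())
            row[f"{var}_12wk_mean"] = f[obs].mean() if obs.any() else np.nan
            row[f"{var}_12wk_sd"] = f[obs].std(ddof=1) if obs.sum() > 1 else 0.0
            # change on complete pairs; PHQ-9 change = baseline - 12wk
            d = sign * (f[obs] - b[obs])
            if obs.any():
                row[f"{var}_change_mean"] = d.mean()
                if len(d) > 1 and n_boot > 0:
                    row[f"{var}_change_ci"] = _bootstrap_ci(d, np.mean, n_boot, rng)
                else:
                    row[f"{var}_change_ci"] = (d.mean(), d.mean())
            else:
                row[f"{var}_change_mean"] = np.nan
                row[f"{var}_change_ci"] = (np.nan, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("arm")
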