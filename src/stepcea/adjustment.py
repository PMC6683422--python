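"""Covariate-adjusted arm estimates.

Randomization does not guarantee balance in baseline severity, age or sex, so
arm comparisons use model-adjusted means: ordinary least squares for the
12-week PHQ-9 and EQ-5D scores (adjusting for the baseline score), and a gamma
GLM with identity link for sector costs (adjusting for age, sex and baseline
PHQ-9).  The gamma family suits right-skewed healthcare costs; the identity
link keeps the mean linear in the predictors so arm contrasts are absolute
dollar differences.

Arm estimates are model predictions at the *pooled* covariate means
(recycled-population standardization), so every arm is evaluated on the same
covariate profile.  Cost models are fitted among service users only (positive
costs); use/non-use is the decision tree's job, making the overall structure a
two-part model.

Estimates from multiply-imputed data are pooled by Rubin's rules: the pooled
point estimate is the mean of the per-imputation estimates and the total
variance is the within-imputation variance plus ``(1 + 1/m)`` times the
between-imputation variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import SECTORS
from .cost_tree import SectorMeans
from .preprocessing import ImputedSet, window_costs

DEFAULT_COST_COVARIATES = ("age", "female", "phq9_baseline")
_BASELINE_FOR = {"phq9_12wk": "phq9_baseline", "eq5d_12wk": "eq5d_baseline"}


class AdjustmentError(ValueError):
    """Model could not be fitted on the given stratum."""


@dataclass(frozen=True)
class AdjustedEstimate:
    """A covariate-adjusted arm mean with its standard error."""

    arm_label: str
    quantity: str
    estimate: float
    standard_error: float
    covariates: tuple[str, ...]
    flag: str = ""

    def __post_init__(self):
        if self.standard_error < 0:
            raise AdjustmentError("standard_error must be >= 0")


def rubin_pool(estimates: Sequence[float], variances: Sequence[float]) -> tuple[float, float]:
    """Pool per-imputation (estimate, variance) pairs; returns (estimate, se)."""
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 1 or len(w) != m:
        raise AdjustmentError("need matching, non-empty estimate/variance sequences")
    qbar = q.mean()
    within = w.mean()
    between = q.var(ddof=1) if m > 1 else 0.0
    total = within + (1 + 1 / m) * between
    return float(qbar), float(np.sqrt(total))


def _design(frame: pd.DataFrame, arms: Sequence[str],
            covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + arm indicators (first arm reference) + covariates."""
    cols = ["const"] + [f"arm_{a}" for a in arms[1:]] + list(covariates)
    X = np.ones((len(frame), len(cols)))
    arm_vals = frame["arm"].to_numpy()
    for j, a in enumerate(arms[1:], start=1):
        X[:, j] = (arm_vals == a).astype(float)
    for j, c in enumerate(covariates, start=1 + len(arms) - 1):
        if c == "female":
            X[:, j] = (frame["sex"] == "female").astype(float)
        else:
            X[:, j] = frame[c].to_numpy(float)
    return X, cols


def _prediction_rows(frame: pd.DataFrame, arms: Sequence[str],
                     covariates: Sequence[str]) -> np.ndarray:
    """One design row per arm at the pooled covariate means."""
    pooled = []
    for c in covariates:
        if c == "female":
            pooled.append((frame["sex"] == "female").mean())
        else:
            pooled.append(frame[c].to_numpy(float).mean())
    rows = np.zeros((len(arms), 1 + len(arms) - 1 + len(covariates)))
    rows[:, 0] = 1.0
    for i in range(1, len(arms)):
        rows[i, i] = 1.0
    rows[:, len(arms):] = pooled
    return rows


def _check_arms(frame: pd.DataFrame, arms: Sequence[str] | None) -> list[str]:
    present = list(dict.fromkeys(frame["arm"]))
    if arms is None:
        return present
    for a in arms:
        if a not in present:
            raise AdjustmentError(f"arm {a!r} has no records (rank-deficient fit)")
    return list(arms)


def fit_outcome_ols(data: pd.DataFrame | ImputedSet, outcome: str,
                    arms: Sequence[str] | None = None) -> dict[str, AdjustedEstimate]:
    """Baseline-adjusted 12-week outcome mean per arm.

    Linear model of the 12-week score on arm indicators and the baseline
    score; arm estimates are predictions at the pooled baseline mean.  For an
    :class:`ImputedSet` the per-imputation estimates are Rubin-pooled.
    """
    if outcome not in _BASELINE_FOR:
        raise AdjustmentError(f"unknown outcome {outcome!r}")
    if isinstance(data, ImputedSet):
        per_arm: dict[str, list[tuple[float, float]]] = {}
        for ds in data.datasets:
            for arm, est in fit_outcome_ols(ds, outcome, arms=arms).items():
                per_arm.setdefault(arm, []).append((est.estimate, est.standard_error**2))
        pooled = {}
        for arm, pairs in per_arm.items():
            e, se = rubin_pool([p[0] for p in pairs], [p[1] for p in pairs])
            pooled[arm] = AdjustedEstimate(arm, outcome, e, se,
                                           (_BASELINE_FOR[outcome], "arm"),
                                           flag=f"rubin_pooled_m{data.m}")
        return pooled

    baseline = _BASELINE_FOR[outcome]
    frame = data.dropna(subset=[outcome, baseline])
    use_arms = _check_arms(frame, arms)
    X, _ = _design(frame, use_arms, [baseline])
    res = sm.OLS(frame[outcome].to_numpy(float), X).fit()
    rows = _prediction_rows(frame, use_arms, [baseline])
    preds = rows @ res.params
    ses = np.sqrt(np.einsum("ij,jk,ik->i", rows, res.cov_params(), rows))
    return {arm: AdjustedEstimate(arm, outcome, float(preds[i]), float(ses[i]),
                                  (baseline, "arm"))
            for i, arm in enumerate(use_arms)}


def sector_users(cohort: pd.DataFrame, sector: str, period: str = "year") -> pd.DataFrame:
    """Records with a positive, untrimmed cost in the sector over the window."""
    if sector not in SECTORS:
        raise AdjustmentError(f"unknown sector {sector!r}")
    cost = window_costs(cohort, period)[sector]
    out = cohort.copy()
    out["_cost"] = cost
    return out[cost > 0].copy()


def fit_cost_glm(data: pd.DataFrame | ImputedSet, sector: str, period: str = "year",
                 covariates: Sequence[str] = DEFAULT_COST_COVARIATES,
                 arms: Sequence[str] | None = None,
                 maxiter: int = 100, tol: float = 1e-8) -> dict[str, AdjustedEstimate]:
    """Gamma-GLM (identity link) adjusted sector cost per arm, among users.

    The frame must already be restricted to users of the sector (every cost
    strictly positive; use :func:`sector_users`).  Fitting is IRLS with a
    fallback start at the OLS coefficients; non-convergence raises with the
    iteration trace.
    """
    if isinstance(data, ImputedSet):
        per_arm: dict[str, list[tuple[float, float, str]]] = {}
        for ds in data.datasets:
            users = sector_users(ds, sector, period)
            for arm, est in fit_cost_glm(users, sector, period, covariates,
                                         arms=arms, maxiter=maxiter, tol=tol).items():
                per_arm.setdefault(arm, []).append(
                    (est.estimate, est.standard_error**2, est.flag))
        pooled = {}
        for arm, triples in per_arm.items():
            e, se = rubin_pool([t[0] for t in triples], [t[1] for t in triples])
            pooled[arm] = AdjustedEstimate(arm, f"cost_{sector}_{period}", e, se,
                                           tuple(covariates) + ("arm",),
                                           flag=f"rubin_pooled_m{data.m}")
        return pooled

    frame = data
    if "_cost" not in frame.columns:
        frame = sector_users(frame, sector, period)
    y = frame["_cost"].to_numpy(float)
    if len(y) == 0:
        raise AdjustmentError(f"no users of sector {sector!r} in period {period!r}")
    if np.any(y <= 0) or np.any(~np.isfinite(y)):
        raise AdjustmentError(
            f"non-positive cost in the {sector} stratum: filter to service users "
            "(positive costs) before fitting the gamma GLM")
    use_arms = _check_arms(frame, arms)
    X, _ = _design(frame, use_arms, covariates)

    with warnings.catch_warnings():
        # identity link is a deliberate non-canonical choice for Gamma
        warnings.simplefilter("ignore")
        family = sm.families.Gamma(link=sm.families.links.Identity())
        model = sm.GLM(y, X, family=family)
        res = None
        errors = []
        for start in (None, "ols"):
            try:
                start_params = (np.linalg.lstsq(X, y, rcond=None)[0]
                                if start == "ols" else None)
                cand = model.fit(start_params=start_params, maxiter=maxiter, tol=tol)
                if np.all(cand.fittedvalues > 0):
                    res = cand
                    break
                errors.append(f"start={start}: non-positive fitted means")
            except Exception as exc:  # noqa: BLE001 - re-raised with trace below
                errors.append(f"start={start}: {exc}")
        if res is None:
            raise AdjustmentError(
                f"gamma GLM did not converge for {sector}/{period} "
                f"(maxiter={maxiter}, tol={tol}): " + "; ".join(errors))

    rows = _prediction_rows(frame, use_arms, covariates)
    preds = rows @ res.params
    ses = np.sqrt(np.einsum("ij,jk,ik->i", rows, res.cov_params(), rows))
    return {arm: AdjustedEstimate(arm, f"cost_{sector}_{period}", float(preds[i]),
                                  float(ses[i]), tuple(covariates) + ("arm",))
            for i, arm in enumerate(use_arms)}


def adjusted_arm_means(cohort: pd.DataFrame, period: str = "year",
                       covariates: Sequence[str] = DEFAULT_COST_COVARIATES,
                       arms: Sequence[str] | None = None,
                       min_users: int = 10) -> dict[str, dict[str, AdjustedEstimate]]:
    """GLM-adjusted user mean cost per arm and sector over a period window.

    Arms contributing fewer than ``min_users`` users to a sector fall back to
    the raw user mean (flagged); an arm-sector with no users at all reports a
    zero placeholder flagged ``no_users`` (its tree branches have probability
    zero).  An arm with zero users of every sector is an error.
    """
    all_arms = _check_arms(cohort, arms)
    out: dict[str, dict[str, AdjustedEstimate]] = {a: {} for a in all_arms}
    any_users = {a: False for a in all_arms}
    for sector in SECTORS:
        users = sector_users(cohort, sector, period)
        counts = users["arm"].value_counts()
        fit_arms = [a for a in all_arms if counts.get(a, 0) >= min_users]
        fitted = {}
        if fit_arms:
            fitted = fit_cost_glm(users[users["arm"].isin(fit_arms)], sector,
                                  period, covariates, arms=fit_arms)
        for arm in all_arms:
            n_arm = int(counts.get(arm, 0))
            if n_arm >= min_users:
                out[arm][sector] = fitted[arm]
            elif n_arm > 0:
                vals = users.loc[users["arm"] == arm, "_cost"].to_numpy(float)
                out[arm][sector] = AdjustedEstimate(
                    arm, f"cost_{sector}_{period}", float(vals.mean()),
                    float(vals.std(ddof=1) / np.sqrt(n_arm)) if n_arm > 1 else 0.0,
                    (), flag="raw_mean_fallback")
            else:
                out[arm][sector] = AdjustedEstimate(
                    arm, f"cost_{sector}_{period}", 0.0, 0.0, (), flag="no_users")
            if n_arm > 0:
                any_users[arm] = True
    for arm, has in any_users.items():
        if not has:
            raise AdjustmentError(f"arm {arm!r} has zero users of every sector")
    return out


def sector_means_table(estimates: Mapping[str, Mapping[str, AdjustedEstimate]]
                       ) -> dict[str, SectorMeans]:
    """Collapse adjusted estimates into per-arm SectorMeans for the cost tree."""
    return {arm: SectorMeans(**{s: max(est[s].estimate, 0.0) for s in SECTORS})
            for arm, est in estimates.items()}
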