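"""Seeded synthetic patient-level cohorts with the trial's statistical structure.

The trial's administrative patient-level data are not deposited; every
downstream stage is therefore exercised on synthetic cohorts whose *summary*
structure matches the published tables:

* four arms (SC, TAU, ICBT, SCP) with the printed per-arm sample sizes,
* PHQ-9 depression scores generated as a two-component mixture — a
  non-depressed component (scores 0-10) and a depressed component (scores
  11-27) — so that the overall mean/sd, the subgroup mean/sd *and* the ~15%
  PHQ-9 > 10 fraction are all matched simultaneously (a single truncated
  normal cannot satisfy all three),
* EQ-5D-5L utilities in [0, 1], negatively correlated with PHQ-9 through a
  Gaussian copula (default correlation -0.5),
* a service-use combination per participant drawn from the arm's published
  service mix, with right-skewed gamma sector costs among users and exact
  zeros for sectors absent from the combination,
* optional injected high-cost outliers and missing 12-week outcomes.

Score marginals are matched by *moment calibration*: the latent normal
parameters are solved numerically so that the clipped (and, for PHQ-9,
rounded) variable reproduces the configured mean and sd, not merely the latent
ones — clipping at the instrument bounds otherwise shifts both.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cost_tree import COMBOS, COMBO_SECTORS, SectorMeans, ServiceMix
from . import published

SECTORS = ("physician", "outpatient", "inpatient")
#: Cost periods: 12 weeks pre-randomization, 12 weeks post, and 12-weeks-to-1-year.
PERIODS = ("pre", "post", "late")
#: Fraction of the post-randomization year covered by each post period.
POST_YEAR_SPLIT = {"post": 12 / 52, "late": 40 / 52}

COST_COLUMNS = tuple(f"cost_{s}_{p}" for s in SECTORS for p in PERIODS)
OUTCOME_12WK_COLUMNS = ("phq9_12wk", "eq5d_12wk")
COLUMNS = ("id", "arm", "age", "sex", "phq9_baseline", "phq9_12wk",
           "eq5d_baseline", "eq5d_12wk", "service_combo") + COST_COLUMNS

MISSING_MECHANISMS = ("MCAR", "MAR_on_baseline")


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


# ---------------------------------------------------------------------------
# Clipped-normal moment calibration
# ---------------------------------------------------------------------------

def clipped_normal_moments(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    """Mean and sd of clip(X, lo, hi) for X ~ Normal(mu, sigma)."""
    if sigma <= 0:
        v = min(max(mu, lo), hi)
        return v, 0.0
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    fa, fb = stats.norm.cdf(a), stats.norm.cdf(b)
    pa, pb = stats.norm.pdf(a), stats.norm.pdf(b)
    z = fb - fa
    m = lo * fa + hi * (1 - fb) + mu * z + sigma * (pa - pb)
    ex2 = (lo**2 * fa + hi**2 * (1 - fb)
           + (mu**2 + sigma**2) * z
           + 2 * mu * sigma * (pa - pb)
           + sigma**2 * (a * pa - b * pb))
    var = max(ex2 - m * m, 0.0)
    return m, var**0.5


def clipped_rounded_normal_moments(mu: float, sigma: float, lo: int, hi: int) -> tuple[float, float]:
    """Mean and sd of round(clip(X, lo, hi)) on the integers lo..hi."""
    if sigma <= 0:
        v = int(min(max(round(mu), lo), hi))
        return float(v), 0.0
    ks = np.arange(lo, hi + 1)
    edges = np.concatenate(([-np.inf], (ks[:-1] + 0.5 - mu) / sigma, [np.inf]))
    cdf = stats.norm.cdf(edges)
    pmf = np.diff(cdf)
    m = float(np.sum(ks * pmf))
    var = float(np.sum((ks - m) ** 2 * pmf))
    return m, var**0.5


@functools.lru_cache(maxsize=512)
def calibrate_clipped_normal(target_mean: float, target_sd: float,
                             lo: float, hi: float, discrete: bool) -> tuple[float, float]:
    """Latent (mu, sigma) whose clipped (and rounded, if discrete) variable
    has the requested mean and sd.

    Raises :class:`ConfigError` when no latent normal can reach the targets
    (e.g. an sd larger than the clip interval supports).
    """
    if not (lo <= target_mean <= hi):
        raise ConfigError(f"target mean {target_mean} outside clip range [{lo}, {hi}]")
    if target_sd < 0:
        raise ConfigError(f"target sd must be >= 0, got {target_sd}")
    if target_sd == 0:
        return float(target_mean), 0.0

    moments = clipped_rounded_normal_moments if discrete else clipped_normal_moments

    def residual(x):
        mu, log_sigma = x
        m, s = moments(mu, float(np.exp(log_sigma)), lo, hi)
        return [m - target_mean, s - target_sd]

    sol = optimize.root(residual, x0=[target_mean, np.log(target_sd)], method="hybr")
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    m, s = moments(mu, sigma, lo, hi)
    if abs(m - target_mean) > 1e-6 * max(1.0, abs(target_mean)) or \
       abs(s - target_sd) > 1e-4 * max(1.0, target_sd):
        raise ConfigError(
            f"cannot calibrate clipped normal to mean={target_mean}, sd={target_sd} "
            f"on [{lo}, {hi}] (best: mean={m:.6g}, sd={s:.6g})")
    return mu, sigma


def complement_moments(p_sub: float, mean_all: float, sd_all: float,
                       mean_sub: float, sd_sub: float) -> tuple[float, float]:
    """Mean and sd of the complement stratum of a two-component mixture.

    Given overall moments and the moments of a subgroup of weight ``p_sub``,
    return the moments of the remaining ``1 - p_sub`` so the mixture
    reproduces the overall mean and sd exactly.
    """
    if not 0 < p_sub < 1:
        raise ConfigError(f"subgroup fraction must be in (0, 1), got {p_sub}")
    q = 1.0 - p_sub
    m = (mean_all - p_sub * mean_sub) / q
    ex2_all = sd_all**2 + mean_all**2
    ex2_sub = sd_sub**2 + mean_sub**2
    var = (ex2_all - p_sub * ex2_sub) / q - m * m
    if var <= 0:
        raise ConfigError(
            f"complement variance non-positive ({var:.4g}); overall and subgroup "
            "moments are incompatible")
    return m, var**0.5


# ---------------------------------------------------------------------------
# Profiles and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepressedProfile:
    """Moments of the depressed stratum (PHQ-9 > 10 at baseline) of one arm."""

    fraction: float
    phq9_baseline_mean: float
    phq9_baseline_sd: float
    phq9_12wk_mean: float
    phq9_12wk_sd: float
    eq5d_baseline_mean: float
    eq5d_baseline_sd: float
    eq5d_12wk_mean: float
    eq5d_12wk_sd: float
    age_mean: float = 45.0
    age_sd: float = 15.0
    female_frac: float = 0.74


@dataclass(frozen=True)
class ArmProfile:
    """Calibration targets for one intervention arm.

    ``phq9_change_mean`` is baseline minus 12 weeks (improvement positive);
    ``eq5d_change_mean`` is 12 weeks minus baseline.  ``sector_means`` and
    ``sector_sds`` give gamma cost moments among service users per period
    ("pre", "post", "late").  When ``depressed`` is set the scores are drawn
    from a two-component mixture whose non-depressed moments are derived by
    complement so the overall targets still hold.
    """

    arm_label: str
    n: int
    phq9_baseline_mean: float
    phq9_baseline_sd: float
    phq9_change_mean: float
    eq5d_baseline_mean: float
    eq5d_baseline_sd: float
    eq5d_change_mean: float
    service_mix: ServiceMix
    sector_means: Mapping[str, SectorMeans]
    sector_sds: Mapping[str, SectorMeans]
    missing_rate: float = 0.0
    phq9_12wk_sd: float | None = None
    eq5d_12wk_sd: float | None = None
    depressed: DepressedProfile | None = None
    age_mean: float = 47.0
    age_sd: float = 17.0
    female_frac: float = 0.73

    def __post_init__(self):
        if self.n < 0:
            raise ConfigError(f"{self.arm_label}: n must be >= 0, got {self.n}")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError(f"{self.arm_label}: missing_rate must be in [0, 1), "
                              f"got {self.missing_rate}")
        for name in ("phq9_baseline_sd",):
            if getattr(self, name) < 0:
                raise ConfigError(f"{self.arm_label}: {name} must be >= 0")
        for period in PERIODS:
            if period not in self.sector_means or period not in self.sector_sds:
                raise ConfigError(f"{self.arm_label}: sector_means/sector_sds must "
                                  f"cover period {period!r}")
        for period in PERIODS:
            for s in SECTORS:
                sd = getattr(self.sector_sds[period], s)
                if not np.isfinite(sd) or sd < 0:
                    raise ConfigError(f"{self.arm_label}: sector sd {s}/{period} "
                                      f"must be finite and >= 0, got {sd}")

    @property
    def phq9_12wk_mean(self) -> float:
        return self.phq9_baseline_mean - self.phq9_change_mean

    @property
    def eq5d_12wk_mean(self) -> float:
        return self.eq5d_baseline_mean + self.eq5d_change_mean


@dataclass(frozen=True)
class CohortConfig:
    """Full generator configuration (one integer seed covers all randomness)."""

    arm_profiles: Sequence[ArmProfile]
    depressed_fraction_target: float = 206 / 1407
    outlier_rate: float = 0.0
    outlier_multiplier: float = 10.0
    seed: int = 0
    phq9_eq5d_corr: float = -0.5
    longitudinal_corr: float = 0.5
    cost_outcome_corr: float = 0.0
    missing_mechanism: str = "MAR_on_baseline"

    def __post_init__(self):
        if not 0 <= self.depressed_fraction_target < 1:
            raise ConfigError("depressed_fraction_target must be in [0, 1)")
        if not 0 <= self.outlier_rate < 1:
            raise ConfigError(f"outlier_rate must be in [0, 1), got {self.outlier_rate}")
        if self.outlier_rate > 0 and self.outlier_multiplier <= 1:
            raise ConfigError("outlier_multiplier must be > 1")
        for name in ("phq9_eq5d_corr", "longitudinal_corr", "cost_outcome_corr"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise ConfigError(f"{name} must be in (-1, 1), got {v}")
        if self.missing_mechanism not in MISSING_MECHANISMS:
            raise ConfigError(f"missing_mechanism must be one of {MISSING_MECHANISMS}")


def default_cohort_config(seed: int = 0, n_per_arm: int | None = None,
                          missing_rate: float = 0.15, outlier_rate: float = 0.05,
                          outlier_multiplier: float = 10.0) -> CohortConfig:
    """The study-condition configuration, calibrated to the published tables.

    Per-arm sample sizes, score moments (overall and depressed subgroup),
    service mixes and one-year sector user costs are the printed values; the
    one-year sector costs are split between the "post" and "late" periods in
    proportion to period length, and the pre-randomization period uses the
    published by-status pre-period costs pooled over depression status.
    """
    pre_means, pre_sds = published.pooled_pre_period_costs()
    profiles = []
    for arm in published.ARMS:
        o = published.OUTCOMES["all"][arm]
        d = published.OUTCOMES["depressed"][arm]
        annual = published.sector_user_means("all", arm)
        annual_sd = SectorMeans(**{s: published.SECTOR_COSTS["all"][arm][s][2]
                                   for s in SECTORS})
        sector_means = {"pre": pre_means}
        sector_sds = {"pre": pre_sds}
        for period, frac in POST_YEAR_SPLIT.items():
            sector_means[period] = SectorMeans(**{s: frac * getattr(annual, s)
                                                  for s in SECTORS})
            sector_sds[period] = SectorMeans(**{s: frac * getattr(annual_sd, s)
                                                for s in SECTORS})
        profiles.append(ArmProfile(
            arm_label=arm, n=n_per_arm if n_per_arm is not None else o.n,
            phq9_baseline_mean=o.phq9_baseline[0], phq9_baseline_sd=o.phq9_baseline[1],
            phq9_change_mean=o.phq9_baseline[0] - o.phq9_12wk[0],
            eq5d_baseline_mean=o.eq5d_baseline[0], eq5d_baseline_sd=o.eq5d_baseline[1],
            eq5d_change_mean=o.eq5d_12wk[0] - o.eq5d_baseline[0],
            phq9_12wk_sd=o.phq9_12wk[1], eq5d_12wk_sd=o.eq5d_12wk[1],
            service_mix=published.service_mix("all", arm),
            sector_means=sector_means, sector_sds=sector_sds,
            missing_rate=missing_rate,
            age_mean=o.age[0], age_sd=o.age[1], female_frac=o.female,
            depressed=DepressedProfile(
                fraction=d.n / o.n,
                phq9_baseline_mean=d.phq9_baseline[0], phq9_baseline_sd=d.phq9_baseline[1],
                phq9_12wk_mean=d.phq9_12wk[0], phq9_12wk_sd=d.phq9_12wk[1],
                eq5d_baseline_mean=d.eq5d_baseline[0], eq5d_baseline_sd=d.eq5d_baseline[1],
                eq5d_12wk_mean=d.eq5d_12wk[0], eq5d_12wk_sd=d.eq5d_12wk[1],
                age_mean=d.age[0], age_sd=d.age[1], female_frac=d.female),
        ))
    return CohortConfig(arm_profiles=tuple(profiles), seed=seed,
                        outlier_rate=outlier_rate,
                        outlier_multiplier=outlier_multiplier)


def pooled_arm_profile(n: int, missing_rate: float = 0.0,
                       label: str = "All") -> ArmProfile:
    """A single profile calibrated to the pooled (all-arm) published moments."""
    base = default_cohort_config(missing_rate=missing_rate)
    template = base.arm_profiles[0]
    o = published.OUTCOMES["all"]["All"]
    d = published.OUTCOMES["depressed"]["All"]
    return replace(
        template, arm_label=label, n=n,
        phq9_baseline_mean=o.phq9_baseline[0], phq9_baseline_sd=o.phq9_baseline[1],
        phq9_change_mean=o.phq9_baseline[0] - o.phq9_12wk[0],
        eq5d_baseline_mean=o.eq5d_baseline[0], eq5d_baseline_sd=o.eq5d_baseline[1],
        eq5d_change_mean=o.eq5d_12wk[0] - o.eq5d_baseline[0],
        phq9_12wk_sd=o.phq9_12wk[1], eq5d_12wk_sd=o.eq5d_12wk[1],
        service_mix=published.service_mix("all", "All"),
        missing_rate=missing_rate,
        age_mean=o.age[0], age_sd=o.age[1], female_frac=o.female,
        depressed=DepressedProfile(
            fraction=d.n / o.n,
            phq9_baseline_mean=d.phq9_baseline[0], phq9_baseline_sd=d.phq9_baseline[1],
            phq9_12wk_mean=d.phq9_12wk[0], phq9_12wk_sd=d.phq9_12wk[1],
            eq5d_baseline_mean=d.eq5d_baseline[0], eq5d_baseline_sd=d.eq5d_baseline[1],
            eq5d_12wk_mean=d.eq5d_12wk[0], eq5d_12wk_sd=d.eq5d_12wk[1],
            age_mean=d.age[0], age_sd=d.age[1], female_frac=d.female))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _component_panels(profile: ArmProfile):
    """(fraction, depressed panel, non-depressed panel) of score/demographic targets.

    Each panel is a dict with keys phq0, phq12, eq0, eq12 (mean, sd tuples),
    age, female.  Without a depressed component a single panel at the overall
    targets is returned with fraction 0.
    """
    phq12_sd = profile.phq9_12wk_sd if profile.phq9_12wk_sd is not None else profile.phq9_baseline_sd
    eq12_sd = profile.eq5d_12wk_sd if profile.eq5d_12wk_sd is not None else profile.eq5d_baseline_sd
    overall = {
        "phq0": (profile.phq9_baseline_mean, profile.phq9_baseline_sd),
        "phq12": (profile.phq9_12wk_mean, phq12_sd),
        "eq0": (profile.eq5d_baseline_mean, profile.eq5d_baseline_sd),
        "eq12": (profile.eq5d_12wk_mean, eq12_sd),
        "age": (profile.age_mean, profile.age_sd),
        "female": profile.female_frac,
    }
    d = profile.depressed
    if d is None:
        return 0.0, None, overall
    dep = {
        "phq0": (d.phq9_baseline_mean, d.phq9_baseline_sd),
        "phq12": (d.phq9_12wk_mean, d.phq9_12wk_sd),
        "eq0": (d.eq5d_baseline_mean, d.eq5d_baseline_sd),
        "eq12": (d.eq5d_12wk_mean, d.eq5d_12wk_sd),
        "age": (d.age_mean, d.age_sd),
        "female": d.female_frac,
    }
    non = {}
    for key in ("phq0", "phq12", "eq0", "eq12", "age"):
        non[key] = complement_moments(d.fraction, *overall[key], *dep[key])
    non["female"] = min(max(
        (overall["female"] - d.fraction * dep["female"]) / (1 - d.fraction), 0.0), 1.0)
    return d.fraction, dep, non


_SCORE_RANGES = {
    # (lo, hi, discrete) per variable; PHQ-9 baseline range depends on stratum
    "phq12": (0, 27, True),
    "eq0": (0.0, 1.0, False),
    "eq12": (0.0, 1.0, False),
}


def _draw_component_scores(panel, z, stratum: str):
    """Clipped (rounded) scores for one mixture component from latent normals z.

    ``z`` has columns (phq0, eq0, phq12, eq12).  ``stratum`` selects the
    baseline PHQ-9 support: 11-27 for "depressed", 0-10 for "non_depressed",
    0-27 for a single-component arm.
    """
    phq0_range = {"depressed": (11, 27), "non_depressed": (0, 10),
                  "single": (0, 27)}[stratum]
    out = {}
    mu, sigma = calibrate_clipped_normal(*panel["phq0"], *phq0_range, True)
    out["phq9_baseline"] = np.floor(np.clip(mu + sigma * z[:, 0], *phq0_range) + 0.5).astype(int)
    for key, col in (("eq0", 1), ("phq12", 2), ("eq12", 3)):
        lo, hi, discrete = _SCORE_RANGES[key]
        mu, sigma = calibrate_clipped_normal(panel[key][0], panel[key][1], lo, hi, discrete)
        vals = np.clip(mu + sigma * z[:, col], lo, hi)
        if discrete:
            vals = np.floor(vals + 0.5)
        out[key] = vals
    return out


def _latent_scores(n: int, rng: np.random.Generator, cross_corr: float,
                   long_corr: float) -> np.ndarray:
    """Latent normals (phq0, eq0, phq12, eq12) with the configured copula.

    Baseline PHQ-9/EQ-5D share correlation ``cross_corr``; each 12-week latent
    carries ``long_corr`` of its own baseline plus an innovation, and the two
    innovations share ``cross_corr`` again, so the 12-week cross-correlation
    equals the baseline one.  Positive semi-definite by construction.
    """
    cov = np.array([[1.0, cross_corr], [cross_corr, 1.0]])
    chol = np.linalg.cholesky(cov)
    base = rng.standard_normal((n, 2)) @ chol.T
    innov = rng.standard_normal((n, 2)) @ chol.T
    fu = long_corr
    twelve = fu * base + np.sqrt(1 - fu * fu) * innov
    return np.column_stack([base[:, 0], base[:, 1], twelve[:, 0], twelve[:, 1]])


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) matched to (mean, sd)."""
    return mean * mean / (sd * sd), sd * sd / mean


def _draw_costs(n: int, mean: float, sd: float, rng: np.random.Generator,
                z_outcome: np.ndarray | None, corr: float) -> np.ndarray:
    """Gamma cost draws, optionally Gaussian-copula-correlated with an outcome latent."""
    if mean == 0:
        return np.zeros(n)
    if sd == 0:
        return np.full(n, mean)
    shape, scale = _gamma_params(mean, sd)
    if z_outcome is None or corr == 0.0:
        return rng.gamma(shape, scale, size=n)
    z = corr * z_outcome + np.sqrt(1 - corr * corr) * rng.standard_normal(n)
    u = stats.norm.cdf(z)
    return stats.gamma.ppf(u, shape, scale=scale)


def _generate_arm(profile: ArmProfile, config: CohortConfig,
                  rng: np.random.Generator, id_start: int) -> pd.DataFrame:
    n = profile.n
    if n == 0:
        return _empty_cohort()
    frac, dep_panel, non_panel = _component_panels(profile)
    is_dep = rng.random(n) < frac if dep_panel is not None else np.zeros(n, bool)

    z = _latent_scores(n, rng, config.phq9_eq5d_corr, config.longitudinal_corr)
    phq0 = np.empty(n, int)
    eq0 = np.empty(n)
    phq12 = np.empty(n)
    eq12 = np.empty(n)
    age = np.empty(n)
    female = np.empty(n, bool)

    strata = [("non_depressed" if dep_panel is not None else "single",
               non_panel, ~is_dep)]
    if dep_panel is not None:
        strata.append(("depressed", dep_panel, is_dep))
    for stratum, panel, mask in strata:
        k = int(mask.sum())
        if k == 0:
            continue
        scores = _draw_component_scores(panel, z[mask], stratum)
        phq0[mask] = scores["phq9_baseline"]
        eq0[mask] = scores["eq0"]
        phq12[mask] = scores["phq12"]
        eq12[mask] = scores["eq12"]
        age[mask] = np.clip(rng.normal(panel["age"][0], panel["age"][1], k), 18, 100)
        female[mask] = rng.random(k) < panel["female"]

    combo_idx = rng.choice(len(COMBOS), size=n, p=profile.service_mix.as_array())
    combos = np.array(COMBOS, dtype=object)[combo_idx]

    data = {
        "id": np.arange(id_start, id_start + n),
        "arm": profile.arm_label,
        "age": np.round(age, 1),
        "sex": np.where(female, "female", "male"),
        "phq9_baseline": phq0,
        "phq9_12wk": phq12,
        "eq5d_baseline": eq0,
        "eq5d_12wk": eq12,
        "service_combo": combos,
    }
    for s_idx, sector in enumerate(SECTORS):
        in_combo = np.isin(combos, [c for c in COMBOS if sector in COMBO_SECTORS[c]])
        for period in PERIODS:
            mean = getattr(profile.sector_means[period], sector)
            sd = getattr(profile.sector_sds[period], sector)
            costs = _draw_costs(n, mean, sd, rng,
                                z[:, 0] if config.cost_outcome_corr else None,
                                config.cost_outcome_corr)
            costs = np.where(in_combo, costs, 0.0)
            data[f"cost_{sector}_{period}"] = np.round(costs, 2)
    return pd.DataFrame(data, columns=COLUMNS)


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=("int64" if c in ("id", "phq9_baseline")
                                             else "object" if c in ("arm", "sex", "service_combo")
                                             else "float64"))
                         for c in COLUMNS})


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one patient-level cohort frame per the configuration.

    Reproducible: identical config (including seed) gives a byte-identical
    CSV serialization.  Outlier injection and missingness are applied last,
    each from a child seed of ``config.seed``.
    """
    gen_seed, outlier_seed, missing_seed = (
        int(s) for s in np.random.SeedSequence(config.seed).generate_state(3) // 2)
    rng = np.random.default_rng(gen_seed)
    frames = []
    id_start = 1
    for profile in config.arm_profiles:
        frame = _generate_arm(profile, config, rng, id_start)
        id_start += profile.n
        frames.append(frame)
    cohort = (pd.concat(frames, ignore_index=True) if frames else _empty_cohort())
    if config.outlier_rate > 0 and len(cohort):
        cohort = inject_outliers(cohort, config.outlier_rate,
                                 config.outlier_multiplier, outlier_seed)
    rates = {p.arm_label: p.missing_rate for p in config.arm_profiles}
    if any(r > 0 for r in rates.values()) and len(cohort):
        parts = []
        for i, (arm, rate) in enumerate(rates.items()):
            sub = cohort[cohort["arm"] == arm]
            parts.append(inject_missingness(sub, rate, config.missing_mechanism,
                                            missing_seed + i) if rate > 0 else sub)
        cohort = pd.concat(parts).sort_values("id").reset_index(drop=True)
    return cohort


def inject_missingness(cohort: pd.DataFrame, rate: float, mechanism: str,
                       seed: int) -> pd.DataFrame:
    """Blank 12-week outcomes for an expected ``rate`` fraction of records.

    ``MCAR`` drops records uniformly; ``MAR_on_baseline`` makes dropout more
    likely for higher baseline PHQ-9 via a logistic model whose intercept is
    solved so the expected missing fraction equals ``rate``.  Baseline fields
    are never removed; both 12-week outcomes go missing together (dropout).
    """
    if not 0 <= rate < 1:
        raise ConfigError(f"missing rate must be in [0, 1), got {rate}")
    if mechanism not in MISSING_MECHANISMS:
        raise ConfigError(f"unknown missingness mechanism {mechanism!r}")
    out = cohort.copy()
    if rate == 0 or len(out) == 0:
        return out
    rng = np.random.default_rng(seed)
    if mechanism == "MCAR":
        p = np.full(len(out), rate)
    else:
        x = out["phq9_baseline"].to_numpy(float)
        sd = x.std()
        zx = (x - x.mean()) / (sd if sd > 0 else 1.0)

        def mean_prob(a):
            return special.expit(a + 1.0 * zx).mean() - rate

        a = optimize.brentq(mean_prob, -30, 30)
        p = special.expit(a + 1.0 * zx)
    mask = rng.random(len(out)) < p
    out.loc[mask, list(OUTCOME_12WK_COLUMNS)] = np.nan
    return out


def inject_outliers(cohort: pd.DataFrame, rate: float, multiplier: float,
                    seed: int) -> pd.DataFrame:
    """Inflate a ``rate`` fraction of physician and outpatient cost cells.

    Inpatient costs are never inflated — they are also never trimmed
    downstream, so contaminating them would bias the analysis by design.
    """
    if not 0 <= rate < 1:
        raise ConfigError(f"outlier rate must be in [0, 1), got {rate}")
    if multiplier <= 1:
        raise ConfigError(f"outlier multiplier must be > 1, got {multiplier}")
    out = cohort.copy()
    if rate == 0 or len(out) == 0:
        return out
    rng = np.random.default_rng(seed)
    for sector in ("physician", "outpatient"):
        for period in PERIODS:
            col = f"cost_{sector}_{period}"
            mask = rng.random(len(out)) < rate
            out.loc[mask, col] = out.loc[mask, col] * multiplier
    return out


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort CSV (one column per field, empty string = missing)."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path, dtype={"arm": str, "sex": str, "service_combo": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"cohort file missing columns: {missing}")
    return df[list(COLUMNS)]
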