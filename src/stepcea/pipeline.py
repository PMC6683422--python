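"""End-to-end analysis orchestration.

``run_full_analysis`` executes the intention-to-treat economic evaluation on a
cohort (generated or loaded): service-combination classification, boxplot
trimming, multiple imputation, covariate adjustment, QALY construction, the
decision-tree cost model, and the Monte Carlo probabilistic sensitivity
analysis with CEAC and scatterplot outputs.  ``table_reproduction`` runs the
decision tree, QALY area-under-curve and PSA directly off the published
summary tables instead of patient-level data.

Every random stage derives its seed from the single configured seed; two runs
with the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import published
from .adjustment import (AdjustedEstimate, adjusted_arm_means, fit_outcome_ols,
                         sector_means_table)
from .cohort import (COST_COLUMNS, CohortConfig, default_cohort_config,
                     generate_cohort, read_cohort)
from .cost_tree import (ExpectedCost, SectorMeans, ServiceMix, estimate_service_mix,
                        expected_cost, pooled_service_mix)
from .effectiveness import ArmQALYs, arm_qaly, qaly_auc
from .preprocessing import (classify_cohort, descriptive_summary,
                            impute_missing, subgroup_depressed, trim_cohort,
                            trim_reports_frame)
from .psa import (ArmDistribution, CEACTable, ICERResult, PSADraws, ceac,
                  fraction_below, icer, plot_ceac, plot_scatter, scatter_points,
                  simulate_psa)

DEFAULT_REFERENCE_ARM = "SCP"
DEFAULT_SCATTER_PAIR = ("SCP", "ICBT")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Options for one full analysis run."""

    cohort: CohortConfig | str | Path | None = None  # None -> default generator
    subgroup: bool = False
    qaly_scenario: str = "carry_forward"
    pooled_mix: bool = False
    n_iter: int = 10_000
    wtp_max: float = 200_000.0
    wtp_step: float = 1_000.0
    seed: int = 0
    m_imputations: int = 20
    trim: bool = True
    trim_factor: float = 1.5
    price_scale: float = 1.0  # CPI adjustment to the 2017 price year
    min_users: int = 10
    reference_arm: str = DEFAULT_REFERENCE_ARM
    scatter_pair: tuple[str, str] = DEFAULT_SCATTER_PAIR
    scatter_wtp: float = 50_000.0

    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_max + self.wtp_step / 2, self.wtp_step)


@dataclass
class AnalysisReport:
    """Everything a run produced, with writers for the standard artifacts."""

    config: AnalysisConfig
    seeds: dict[str, int]
    cohort: pd.DataFrame
    descriptives: pd.DataFrame
    trim_reports: pd.DataFrame
    service_mixes: dict[str, ServiceMix]
    sector_estimates: dict[str, dict[str, AdjustedEstimate]]
    expected_costs: dict[str, ExpectedCost]
    cost_sds: dict[str, float]
    qalys: ArmQALYs
    arm_distributions: list[ArmDistribution]
    draws: PSADraws
    icers: dict[str, ICERResult]
    ceac_table: CEACTable
    scatter: pd.DataFrame
    scatter_fraction: float
    log: list[str] = dc_field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        """Per-arm totals and QALYs (the headline cost-effectiveness table)."""
        rows = []
        for arm, ec in self.expected_costs.items():
            q = self.qalys.values[arm]
            rows.append({"arm": arm, "total_cost": ec.total,
                         "cost_sd": self.cost_sds[arm],
                         "qaly": q.qaly, "qaly_se": q.standard_error})
        return pd.DataFrame(rows).set_index("arm")

    def write(self, outdir, plots: bool = False) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptives.to_csv(out / "descriptives.csv")
        self.trim_reports.to_csv(out / "trim_report.csv", index=False)
        mix_rows = [{"arm": a, **dict(zip(
            ("p_none", "p_phys", "p_phys_out", "p_phys_inp", "p_all"),
            m.as_array()))} for a, m in self.service_mixes.items()]
        pd.DataFrame(mix_rows).to_csv(out / "service_mix.csv", index=False)
        est_rows = [{"arm": a, "sector": s, "estimate": e.estimate,
                     "standard_error": e.standard_error, "flag": e.flag}
                    for a, per in self.sector_estimates.items()
                    for s, e in per.items()]
        pd.DataFrame(est_rows).to_csv(out / "adjusted_costs.csv", index=False)
        self.summary_frame().to_csv(out / "summary.csv")
        self.ceac_table.to_long_frame().to_csv(out / "ceac.csv", index=False)
        self.scatter.to_csv(out / "scatter.csv", index=False)
        summary = {
            "seeds": self.seeds,
            "scatter_pair": list(self.config.scatter_pair),
            "scatter_wtp": self.config.scatter_wtp,
            "scatter_fraction_below": self.scatter_fraction,
            "qaly_scenario": self.config.qaly_scenario,
            "subgroup": self.config.subgroup,
            "pooled_mix": self.config.pooled_mix,
            "price_scale": self.config.price_scale,
            "icers": {a: {"delta_cost": r.delta_cost, "delta_qaly": r.delta_qaly,
                          "quadrant": r.quadrant, "ratio": r.ratio,
                          "degenerate": r.degenerate}
                      for a, r in self.icers.items()},
            "log": self.log,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        if plots:
            plot_ceac(self.ceac_table, path=out / "ceac.png")
            plot_scatter(self.scatter, wtp=self.config.scatter_wtp,
                         path=out / "scatter.png")


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __init__(self, label):
            self.label = label

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {self.label!r} failed: {exc}") from exc
            return False
    return _Ctx(name)


def _tree_total_sd(mix: ServiceMix, estimates: Mapping[str, AdjustedEstimate],
                   n_arm: int) -> float:
    """Delta-method sd of the tree total.

    Combines multinomial uncertainty in the mix probabilities with the
    (assumed independent) standard errors of the adjusted sector user means.
    """
    from .cost_tree import branch_costs
    p = mix.as_array()
    means = SectorMeans(**{s: max(estimates[s].estimate, 0.0)
                           for s in ("physician", "outpatient", "inpatient")})
    c = branch_costs(means)
    cov_p = (np.diag(p) - np.outer(p, p)) / max(n_arm, 1)
    var = float(c @ cov_p @ c)
    grads = {"physician": 1 - p[0],
             "outpatient": p[2] + p[4],
             "inpatient": p[3] + p[4]}
    for s, g in grads.items():
        var += (g * estimates[s].standard_error) ** 2
    return var**0.5


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the full evaluation; see the module docstring for the stages."""
    seed_seq = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s) for name, s in zip(
        ("impute", "psa", "descriptives"), seed_seq.generate_state(3) // 2)}
    log: list[str] = []

    with _stage("load_or_generate"):
        if config.cohort is None:
            cohort_cfg = default_cohort_config(seed=config.seed)
            cohort = generate_cohort(cohort_cfg)
            log.append(f"generated default cohort, seed={config.seed}, n={len(cohort)}")
        elif isinstance(config.cohort, CohortConfig):
            cohort = generate_cohort(config.cohort)
            log.append(f"generated cohort from config, seed={config.cohort.seed}, "
                       f"n={len(cohort)}")
        else:
            cohort = read_cohort(config.cohort)
            log.append(f"loaded cohort from {config.cohort}, n={len(cohort)}")

    with _stage("price_adjustment"):
        if config.price_scale != 1.0:
            cohort = cohort.copy()
            cohort[list(COST_COLUMNS)] = cohort[list(COST_COLUMNS)] * config.price_scale
            log.append(f"costs rescaled to price year by factor {config.price_scale}")

    with _stage("classify"):
        cohort = cohort.copy()
        cohort["service_combo"] = classify_cohort(cohort, window="year")

    with _stage("subgroup"):
        if config.subgroup:
            cohort = subgroup_depressed(cohort)
            log.append(f"depressed subgroup: n={len(cohort)}")

    arms = list(dict.fromkeys(cohort["arm"]))

    with _stage("descriptives"):
        descriptives = descriptive_summary(cohort, n_boot=200,
                                           seed=stage_seeds["descriptives"])

    with _stage("trim"):
        if config.trim:
            trimmed, reports = trim_cohort(cohort, factor=config.trim_factor)
            log.append(f"trimmed {sum(r.n_removed for r in reports)} cost observations")
        else:
            trimmed, reports = cohort, []
            log.append("trimming disabled")
        trim_frame = trim_reports_frame(reports)

    with _stage("impute"):
        imputed = impute_missing(trimmed, m=config.m_imputations,
                                 seed=stage_seeds["impute"])
        log.append(f"multiple imputation: m={imputed.m}, method={imputed.method}")

    with _stage("service_mix"):
        if config.pooled_mix:
            pooled = pooled_service_mix(cohort)
            mixes = {arm: pooled for arm in arms}
            log.append("sensitivity scenario: identical pooled service mix in all arms")
        else:
            mixes = {arm: estimate_service_mix(cohort, arm) for arm in arms}

    with _stage("adjust_costs"):
        sector_estimates = adjusted_arm_means(trimmed, period="year", arms=arms,
                                              min_users=config.min_users)
        flags = [f"{a}/{s}:{e.flag}" for a, per in sector_estimates.items()
                 for s, e in per.items() if e.flag]
        if flags:
            log.append("cost estimate flags: " + ", ".join(flags))

    with _stage("cost_tree"):
        means = sector_means_table(sector_estimates)
        expected = {arm: expected_cost(mixes[arm], means[arm], arm_label=arm)
                    for arm in arms}
        arm_n = cohort["arm"].value_counts()
        cost_sds = {arm: _tree_total_sd(mixes[arm], sector_estimates[arm],
                                        int(arm_n[arm])) for arm in arms}

    with _stage("qaly"):
        adjusted_u12 = fit_outcome_ols(imputed, "eq5d_12wk", arms=arms)
        utilities = {}
        for arm in arms:
            g = cohort[cohort["arm"] == arm]
            u0 = float(g["eq5d_baseline"].mean())
            se0 = float(g["eq5d_baseline"].std(ddof=1) / np.sqrt(len(g))) if len(g) > 1 else 0.0
            est = adjusted_u12[arm]
            utilities[arm] = (u0, min(max(est.estimate, 0.0), 1.0),
                              se0, est.standard_error)
        reference = (config.reference_arm if config.reference_arm in arms
                     else arms[0])
        qalys = arm_qaly(utilities, scenario=config.qaly_scenario,
                         reference=reference)

    with _stage("psa"):
        dists = [ArmDistribution(arm_label=arm,
                                 cost_mean=expected[arm].total,
                                 cost_sd=cost_sds[arm],
                                 qaly_mean=qalys.values[arm].qaly,
                                 qaly_sd=qalys.values[arm].standard_error)
                 for arm in arms]
        draws = simulate_psa(dists, n_iter=config.n_iter, seed=stage_seeds["psa"])

    with _stage("ceac_scatter"):
        table = ceac(draws, config.wtp_grid())
        points_estimates = {arm: (expected[arm].total, qalys.values[arm].qaly)
                            for arm in arms}
        icers = {arm: icer(points_estimates, reference, arm)
                 for arm in arms if arm != reference}
        a, b = config.scatter_pair
        if a in arms and b in arms:
            scatter = scatter_points(draws, a, b)
            frac = fraction_below(scatter, config.scatter_wtp)
        else:
            scatter = pd.DataFrame(columns=["iteration", "delta_qaly", "delta_cost"])
            frac = float("nan")
            log.append(f"scatter pair {config.scatter_pair} not present; skipped")

    return AnalysisReport(config=config, seeds={"root": config.seed, **stage_seeds},
                          cohort=cohort, descriptives=descriptives,
                          trim_reports=trim_frame, service_mixes=mixes,
                          sector_estimates=sector_estimates,
                          expected_costs=expected, cost_sds=cost_sds, qalys=qalys,
                          arm_distributions=dists, draws=draws, icers=icers,
                          ceac_table=table, scatter=scatter,
                          scatter_fraction=frac, log=log)


# ---------------------------------------------------------------------------
# Table-reproduction mode
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableReproduction:
    """Results computed directly from the published summary tables."""

    population: str
    expected_costs: dict[str, ExpectedCost]
    qalys: dict[str, float]
    draws: PSADraws
    ceac_table: CEACTable
    scatter: pd.DataFrame
    scatter_fraction: float


def table_reproduction(population: str = "all", n_iter: int = 10_000,
                       seed: int = 0, scenario: str = "carry_forward",
                       scatter_pair: tuple[str, str] = DEFAULT_SCATTER_PAIR,
                       scatter_wtp: float = 50_000.0,
                       wtp_grid: np.ndarray | None = None) -> TableReproduction:
    """Run tree, QALY AUC and PSA off the printed tables (no patient data).

    The decision tree combines each arm's printed service-mix counts with its
    printed one-year sector user means; QALYs apply the persistence scenario
    to the printed baseline and 12-week utilities; the PSA samples each arm's
    total cost (gamma) and QALY (truncated normal) from the printed
    cost-effectiveness table means and s.d.
    """
    expected = {}
    qalys = {}
    for arm in published.ARMS:
        mix = published.service_mix(population, arm)
        means = published.sector_user_means(population, arm)
        expected[arm] = expected_cost(mix, means, arm_label=arm)
        o = published.OUTCOMES[population][arm]
        qalys[arm] = qaly_auc(o.eq5d_baseline[0], o.eq5d_12wk[0], scenario).value
    dists = published.cea_arm_distributions(population)
    draws = simulate_psa(dists, n_iter=n_iter, seed=seed)
    table = ceac(draws, wtp_grid)
    scatter = scatter_points(draws, *scatter_pair)
    frac = fraction_below(scatter, scatter_wtp)
    return TableReproduction(population=population, expected_costs=expected,
                             qalys=qalys, draws=draws, ceac_table=table,
                             scatter=scatter, scatter_fraction=frac)
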