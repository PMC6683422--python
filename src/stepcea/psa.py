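"""Probabilistic sensitivity analysis: Monte Carlo ICERs, NMB, CEACs, scatterplots.

Parameter uncertainty in each arm's mean cost and mean QALY is propagated by
sampling both from "known probability distributions" — by default a gamma for
costs (right-skewed, non-negative) and a normal truncated to [0, 1] for QALYs
— and recomputing the incremental quantities in every iteration.  At a
willingness-to-pay λ the net monetary benefit of arm a against arm b is

    NMB_i = λ · (qaly_a,i − qaly_b,i) − (cost_a,i − cost_b,i)

and the cost-effectiveness acceptability curve (CEAC) reports, for each λ on a
grid, the fraction of iterations in which an arm attains the maximum NMB among
all arms (ties split equally).  The incremental cost-effectiveness scatterplot
plots the paired (ΔQALY, Δcost) draws; the fraction of points below the λ line
(Δcost < λ·ΔQALY) for a pair of arms equals the pairwise CEAC value at λ by
definition.

Arms are sampled independently by default; a correlation knob couples an arm's
cost and QALY draws through a Gaussian copula when set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_ITER = 10_000
DEFAULT_WTP_GRID = np.arange(0, 200_001, 1_000)

COST_FAMILIES = ("gamma", "normal")
QALY_FAMILIES = ("truncnorm", "normal")


class PSAError(ValueError):
    """Invalid PSA inputs."""


@dataclass(frozen=True)
class ArmDistribution:
    """Sampling distribution of one arm's mean cost and mean QALY."""

    arm_label: str
    cost_mean: float
    cost_sd: float
    qaly_mean: float
    qaly_sd: float
    cost_family: str = "gamma"
    qaly_family: str = "truncnorm"

    def __post_init__(self):
        if self.cost_sd < 0 or self.qaly_sd < 0:
            raise PSAError(f"{self.arm_label}: sd must be >= 0")
        if self.cost_mean < 0:
            raise PSAError(f"{self.arm_label}: cost_mean must be >= 0")
        if self.cost_family not in COST_FAMILIES:
            raise PSAError(f"{self.arm_label}: unknown cost family {self.cost_family!r}")
        if self.qaly_family not in QALY_FAMILIES:
            raise PSAError(f"{self.arm_label}: unknown qaly family {self.qaly_family!r}")


@dataclass(frozen=True)
class PSADraws:
    """Paired (cost, QALY) Monte Carlo draws per arm (same n_iter everywhere)."""

    costs: Mapping[str, np.ndarray]
    qalys: Mapping[str, np.ndarray]
    n_iter: int
    seed: int

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(self.costs)

    def require_arm(self, arm: str) -> None:
        if arm not in self.costs:
            raise PSAError(f"arm {arm!r} not present in draws")


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost-effectiveness of arm_a versus arm_b.

    ``ratio`` is reported only in trade-off quadrants; a dominant (cheaper and
    more effective) or dominated (costlier and less effective) comparison has
    no meaningful ratio, and ΔQALY = 0 is flagged degenerate.
    """

    arm_a: str
    arm_b: str
    delta_cost: float
    delta_qaly: float
    quadrant: str  # dominant | dominated | trade-off
    ratio: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class CEACTable:
    """Per-arm probability of being cost-effective over a willingness-to-pay grid."""

    wtp: np.ndarray
    probabilities: pd.DataFrame  # index: wtp, columns: arms

    def at(self, wtp: float) -> pd.Series:
        idx = int(np.argmin(np.abs(self.wtp - wtp)))
        return self.probabilities.iloc[idx]

    def to_long_frame(self) -> pd.DataFrame:
        long = self.probabilities.reset_index().melt(
            id_vars="wtp", var_name="arm", value_name="probability")
        return long.sort_values(["wtp", "arm"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_cost(dist: ArmDistribution, z: np.ndarray) -> np.ndarray:
    if dist.cost_sd == 0:
        return np.full(len(z), dist.cost_mean)
    if dist.cost_family == "normal":
        return dist.cost_mean + dist.cost_sd * z
    shape = dist.cost_mean**2 / dist.cost_sd**2
    scale = dist.cost_sd**2 / dist.cost_mean
    return stats.gamma.ppf(stats.norm.cdf(z), shape, scale=scale)


def _sample_qaly(dist: ArmDistribution, z: np.ndarray) -> np.ndarray:
    if dist.qaly_sd == 0:
        return np.full(len(z), dist.qaly_mean)
    if dist.qaly_family == "normal":
        return dist.qaly_mean + dist.qaly_sd * z
    a = (0.0 - dist.qaly_mean) / dist.qaly_sd
    b = (1.0 - dist.qaly_mean) / dist.qaly_sd
    return stats.truncnorm.ppf(stats.norm.cdf(z), a, b,
                               loc=dist.qaly_mean, scale=dist.qaly_sd)


def simulate_psa(dists: Sequence[ArmDistribution], n_iter: int = DEFAULT_N_ITER,
                 seed: int = 0, cost_qaly_corr: float = 0.0) -> PSADraws:
    """Draw n_iter (cost, QALY) pairs per arm; seeded and reproducible.

    All families are sampled through a latent standard normal (inverse-CDF),
    so ``cost_qaly_corr`` induces a within-arm Gaussian-copula correlation
    between an arm's cost and QALY draws (default 0: independent).
    """
    if n_iter < 1:
        raise PSAError(f"n_iter must be >= 1, got {n_iter}")
    if not -1 < cost_qaly_corr < 1:
        raise PSAError(f"cost_qaly_corr must be in (-1, 1), got {cost_qaly_corr}")
    if len({d.arm_label for d in dists}) != len(dists):
        raise PSAError("duplicate arm labels in distributions")
    rng = np.random.default_rng(seed)
    costs, qalys = {}, {}
    r = cost_qaly_corr
    for dist in dists:
        zc = rng.standard_normal(n_iter)
        zq = r * zc + np.sqrt(1 - r * r) * rng.standard_normal(n_iter)
        costs[dist.arm_label] = _sample_cost(dist, zc)
        qalys[dist.arm_label] = _sample_qaly(dist, zq)
    return PSADraws(costs=costs, qalys=qalys, n_iter=n_iter, seed=seed)


# ---------------------------------------------------------------------------
# Incremental quantities
# ---------------------------------------------------------------------------

def icer(points: PSADraws | Mapping[str, tuple[float, float]],
         arm_a: str, arm_b: str) -> ICERResult:
    """ICER of arm_a versus arm_b from draws (means) or point estimates.

    ``points`` is either :class:`PSADraws` (arm means of the draws are used)
    or a mapping arm -> (cost, qaly).
    """
    if isinstance(points, PSADraws):
        points.require_arm(arm_a)
        points.require_arm(arm_b)
        ca, qa = points.costs[arm_a].mean(), points.qalys[arm_a].mean()
        cb, qb = points.costs[arm_b].mean(), points.qalys[arm_b].mean()
    else:
        try:
            ca, qa = points[arm_a]
            cb, qb = points[arm_b]
        except KeyError as exc:
            raise PSAError(f"arm {exc.args[0]!r} not present") from None
    dc, dq = float(ca - cb), float(qa - qb)
    if dc < 0 and dq > 0:
        return ICERResult(arm_a, arm_b, dc, dq, "dominant")
    if dc > 0 and dq < 0:
        return ICERResult(arm_a, arm_b, dc, dq, "dominated")
    if dq == 0:
        return ICERResult(arm_a, arm_b, dc, dq, "trade-off", ratio=None,
                          degenerate=True)
    return ICERResult(arm_a, arm_b, dc, dq, "trade-off", ratio=dc / dq)


def incremental_nmb(draws: PSADraws, arm_a: str, arm_b: str,
                    wtp: float) -> np.ndarray:
    """Per-draw net monetary benefit of arm_a over arm_b at willingness-to-pay wtp."""
    draws.require_arm(arm_a)
    draws.require_arm(arm_b)
    qa, qb = draws.qalys[arm_a], draws.qalys[arm_b]
    ca, cb = draws.costs[arm_a], draws.costs[arm_b]
    if len(qa) != len(qb):
        raise PSAError("mismatched draw counts between arms")
    return wtp * (qa - qb) - (ca - cb)


def ceac(draws: PSADraws, wtp_grid: np.ndarray | None = None,
         tie_tol: float = 1e-9) -> CEACTable:
    """Multi-way CEAC: P(arm has max NMB) over the willingness-to-pay grid.

    Ties within ``tie_tol`` of the maximum split their iteration's weight
    equally (a measure-zero event for continuous families, but well defined
    for sd = 0 fixtures), so probabilities sum to exactly 1 at every λ.
    """
    if len(draws.arms) < 2:
        raise PSAError("CEAC requires at least two arms")
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise PSAError("empty willingness-to-pay grid")
    arms = draws.arms
    C = np.vstack([draws.costs[a] for a in arms])
    Q = np.vstack([draws.qalys[a] for a in arms])
    probs = np.empty((grid.size, len(arms)))
    for i, wtp in enumerate(grid):
        nmb = wtp * Q - C
        top = nmb.max(axis=0)
        is_max = nmb >= top - tie_tol
        weights = is_max / is_max.sum(axis=0)
        probs[i] = weights.mean(axis=1)
    frame = pd.DataFrame(probs, columns=list(arms),
                         index=pd.Index(grid, name="wtp"))
    return CEACTable(wtp=grid, probabilities=frame)


def ceac_pairwise(draws: PSADraws, arm_a: str, arm_b: str,
                  wtp_grid: np.ndarray | None = None) -> pd.Series:
    """P(arm_a cost-effective vs arm_b) over the grid; equals the fraction of
    scatter points below each λ line."""
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise PSAError("empty willingness-to-pay grid")
    vals = [float((incremental_nmb(draws, arm_a, arm_b, w) > 0).mean()) for w in grid]
    return pd.Series(vals, index=pd.Index(grid, name="wtp"),
                     name=f"{arm_a}_vs_{arm_b}")


def scatter_points(draws: PSADraws, arm_a: str, arm_b: str) -> pd.DataFrame:
    """Paired incremental (ΔQALY, Δcost) points for the cost-effectiveness plane."""
    draws.require_arm(arm_a)
    draws.require_arm(arm_b)
    dq = draws.qalys[arm_a] - draws.qalys[arm_b]
    dc = draws.costs[arm_a] - draws.costs[arm_b]
    return pd.DataFrame({"iteration": np.arange(len(dq)),
                         "delta_qaly": dq, "delta_cost": dc})


def fraction_below(points: pd.DataFrame, wtp: float) -> float:
    """Fraction of scatter points below the willingness-to-pay line
    (Δcost < wtp·ΔQALY), i.e. where the first arm is cost-effective."""
    return float((points["delta_cost"] < wtp * points["delta_qaly"]).mean())


# ---------------------------------------------------------------------------
# Plots (matplotlib imported lazily so headless use stays cheap)
# ---------------------------------------------------------------------------

def plot_ceac(table: CEACTable, path=None, title: str = "Cost-effectiveness acceptability curves"):
    """Plot each arm's acceptability curve; write to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for arm in table.probabilities.columns:
        ax.plot(table.wtp, table.probabilities[arm], label=arm)
    ax.set_xlabel("Willingness-to-pay (CAD per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_scatter(points: pd.DataFrame, wtp: float = 50_000, path=None,
                 title: str = "Incremental cost-effectiveness scatterplot"):
    """Plot the incremental cost-QALY cloud with the λ threshold line."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(points["delta_qaly"], points["delta_cost"], s=3, alpha=0.3)
    xs = np.array([points["delta_qaly"].min(), points["delta_qaly"].max()])
    ax.plot(xs, wtp * xs, "k--", label=f"λ = {wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (CAD)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
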