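"""Monte Carlo PSA: sampling, ICER quadrants, NMB, CEAC, scatterplots."""

import itertools

import numpy as np
import pytest
from scipy import stats

import stepcea as sc
from stepcea import published


def two_arm_normal_draws(mu_c, sd_c, mu_q, sd_q, n_iter=20_000, seed=0):
    dists = [
        sc.ArmDistribution("A", mu_c[0], sd_c[0], mu_q[0], sd_q[0],
                           cost_family="normal", qaly_family="normal"),
        sc.ArmDistribution("B", mu_c[1], sd_c[1], mu_q[1], sd_q[1],
                           cost_family="normal", qaly_family="normal"),
    ]
    return sc.simulate_psa(dists, n_iter=n_iter, seed=seed)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def test_zero_sd_draws_equal_means():
    dists = [sc.ArmDistribution("A", 2000.0, 0.0, 0.88, 0.0)]
    draws = sc.simulate_psa(dists, n_iter=50, seed=1)
    assert np.all(draws.costs["A"] == 2000.0)
    assert np.all(draws.qalys["A"] == 0.88)


def test_same_seed_identical_draws():
    dists = published.cea_arm_distributions("all")
    a = sc.simulate_psa(dists, n_iter=500, seed=9)
    b = sc.simulate_psa(dists, n_iter=500, seed=9)
    for arm in a.arms:
        assert np.array_equal(a.costs[arm], b.costs[arm])
        assert np.array_equal(a.qalys[arm], b.qalys[arm])


def test_published_parameter_convergence():
    """Sample means at 10,000 iterations sit within 3 se of the inputs."""
    dists = published.cea_arm_distributions("all")
    draws = sc.simulate_psa(dists, n_iter=10_000, seed=3)
    for d in dists:
        se_c = d.cost_sd / np.sqrt(draws.n_iter)
        assert draws.costs[d.arm_label].mean() == pytest.approx(d.cost_mean,
                                                                abs=3 * se_c)
        se_q = d.qaly_sd / np.sqrt(draws.n_iter)
        # truncation at [0,1] barely moves these means (>= 10 sd from bounds)
        assert draws.qalys[d.arm_label].mean() == pytest.approx(d.qaly_mean,
                                                                abs=3 * se_q + 1e-4)


def test_invalid_distributions_rejected():
    with pytest.raises(sc.PSAError):
        sc.ArmDistribution("A", 100.0, -1.0, 0.8, 0.01)
    dists = [sc.ArmDistribution("A", 100.0, 10.0, 0.8, 0.01)]
    with pytest.raises(sc.PSAError):
        sc.simulate_psa(dists, n_iter=0)


def test_cost_qaly_correlation_knob():
    dists = [sc.ArmDistribution("A", 2000.0, 300.0, 0.8, 0.05)]
    draws = sc.simulate_psa(dists, n_iter=30_000, seed=5, cost_qaly_corr=0.7)
    r = np.corrcoef(draws.costs["A"], draws.qalys["A"])[0, 1]
    assert r == pytest.approx(0.7, abs=0.05)


# ---------------------------------------------------------------------------
# ICER
# ---------------------------------------------------------------------------

def icer_oracle(dc, dq):
    """Sign-table oracle for the quadrant/ratio rules."""
    if dc < 0 and dq > 0:
        return "dominant", None, False
    if dc > 0 and dq < 0:
        return "dominated", None, False
    if dq == 0:
        return "trade-off", None, True
    return "trade-off", dc / dq, False


@pytest.mark.parametrize("dc,dq", list(itertools.product((-500.0, 0.0, 500.0),
                                                         (-0.01, 0.0, 0.01))))
def test_icer_quadrants_match_sign_table(dc, dq):
    points = {"a": (1000.0 + dc, 0.8 + dq), "b": (1000.0, 0.8)}
    res = sc.icer(points, "a", "b")
    quadrant, ratio, degenerate = icer_oracle(dc, dq)
    assert res.quadrant == quadrant
    assert res.degenerate == degenerate
    if ratio is None:
        assert res.ratio is None
    else:
        assert res.ratio == pytest.approx(ratio)


def test_icer_published_scp_vs_tau_dominant():
    """SCP vs TAU: cheaper (-$549) and more effective (+0.0124 QALY)."""
    points = {arm: (row["total"][0], row["qaly"][0])
              for arm, row in published.CEA_RESULTS["all"].items()}
    res = sc.icer(points, "SCP", "TAU")
    assert res.quadrant == "dominant"
    assert res.delta_cost == pytest.approx(-549.0)
    # the reported difference (0.0124) carries more decimals than the printed
    # per-arm QALYs (0.882, 0.870), so agreement is to the printed precision
    assert res.delta_qaly == pytest.approx(0.0124, abs=1e-3)


def test_icer_simple_ratio():
    res = sc.icer({"a": (1500.0, 0.81), "b": (1000.0, 0.80)}, "a", "b")
    assert res.ratio == pytest.approx(50_000.0)


def test_icer_from_draws_uses_means():
    draws = two_arm_normal_draws((1200, 1000), (1, 1), (0.82, 0.80), (0.0, 0.0),
                                 n_iter=5_000, seed=2)
    res = sc.icer(draws, "A", "B")
    assert res.ratio == pytest.approx(200 / 0.02, rel=0.01)


# ---------------------------------------------------------------------------
# NMB
# ---------------------------------------------------------------------------

def test_nmb_at_zero_wtp_is_negative_delta_cost():
    draws = two_arm_normal_draws((1200, 1000), (50, 50), (0.8, 0.8), (0.01, 0.01),
                                 n_iter=1_000, seed=4)
    nmb = sc.incremental_nmb(draws, "A", "B", wtp=0.0)
    dc = draws.costs["A"] - draws.costs["B"]
    assert np.allclose(nmb, -dc)


def test_nmb_sign_flips_at_large_wtp():
    draws = two_arm_normal_draws((1200, 1000), (0, 0), (0.82, 0.80), (0.0, 0.0),
                                 n_iter=10, seed=4)
    assert np.all(sc.incremental_nmb(draws, "A", "B", wtp=1e7) > 0)


def test_nmb_closed_form_moments():
    """Independent normal draws: NMB mean/variance match theory within MC error."""
    mu_c, sd_c = (1300.0, 1000.0), (200.0, 150.0)
    mu_q, sd_q = (0.84, 0.80), (0.02, 0.015)
    wtp = 50_000.0
    n = 40_000
    draws = two_arm_normal_draws(mu_c, sd_c, mu_q, sd_q, n_iter=n, seed=6)
    nmb = sc.incremental_nmb(draws, "A", "B", wtp)
    mean_theory = wtp * (mu_q[0] - mu_q[1]) - (mu_c[0] - mu_c[1])
    var_theory = wtp**2 * (sd_q[0]**2 + sd_q[1]**2) + sd_c[0]**2 + sd_c[1]**2
    assert nmb.mean() == pytest.approx(mean_theory,
                                       abs=3 * np.sqrt(var_theory / n))
    assert nmb.var() == pytest.approx(var_theory, rel=0.05)


# ---------------------------------------------------------------------------
# CEAC
# ---------------------------------------------------------------------------

def test_ceac_dominant_arm_curve_is_one():
    dists = [sc.ArmDistribution("win", 100.0, 0.0, 0.9, 0.0),
             sc.ArmDistribution("lose", 500.0, 0.0, 0.7, 0.0)]
    draws = sc.simulate_psa(dists, n_iter=100, seed=1)
    table = sc.ceac(draws, np.array([0.0, 50_000.0, 200_000.0]))
    assert np.all(table.probabilities["win"] == 1.0)
    assert np.all(table.probabilities["lose"] == 0.0)


def test_ceac_probabilities_sum_to_one():
    dists = published.cea_arm_distributions("all")
    draws = sc.simulate_psa(dists, n_iter=2_000, seed=8)
    table = sc.ceac(draws, np.arange(0, 200_001, 20_000, dtype=float))
    sums = table.probabilities.sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert ((table.probabilities >= 0) & (table.probabilities <= 1)).all().all()


def test_ceac_matches_closed_form_normal_oracle():
    """Two independent normal arms: CEAC equals Phi((wtp*dE - dC)/sigma_NMB)."""
    mu_c, sd_c = (1300.0, 1000.0), (220.0, 180.0)
    mu_q, sd_q = (0.83, 0.81), (0.02, 0.018)
    n = 20_000
    draws = two_arm_normal_draws(mu_c, sd_c, mu_q, sd_q, n_iter=n, seed=10)
    grid = np.array([0.0, 10_000.0, 30_000.0, 50_000.0, 100_000.0, 200_000.0])
    table = sc.ceac(draws, grid)
    for wtp in grid:
        mean = wtp * (mu_q[0] - mu_q[1]) - (mu_c[0] - mu_c[1])
        sd = np.sqrt(wtp**2 * (sd_q[0]**2 + sd_q[1]**2) + sd_c[0]**2 + sd_c[1]**2)
        p = stats.norm.cdf(mean / sd)
        mc_se = np.sqrt(p * (1 - p) / n)
        assert table.probabilities.loc[wtp, "A"] == pytest.approx(
            p, abs=3 * mc_se + 1e-4)


def test_ceac_endpoints_rank_by_cost_then_qaly():
    """wtp=0 ranks purely by cost; very large wtp purely by QALY."""
    dists = [sc.ArmDistribution("cheap_bad", 100.0, 0.0, 0.5, 0.0),
             sc.ArmDistribution("dear_good", 900.0, 0.0, 0.9, 0.0)]
    draws = sc.simulate_psa(dists, n_iter=10, seed=0)
    table = sc.ceac(draws, np.array([0.0, 1e7]))
    assert table.probabilities.loc[0.0, "cheap_bad"] == 1.0
    assert table.probabilities.loc[1e7, "dear_good"] == 1.0


def test_ceac_ties_split_equally():
    dists = [sc.ArmDistribution("A", 100.0, 0.0, 0.8, 0.0),
             sc.ArmDistribution("B", 100.0, 0.0, 0.8, 0.0)]
    draws = sc.simulate_psa(dists, n_iter=10, seed=0)
    table = sc.ceac(draws, np.array([50_000.0]))
    assert table.probabilities.iloc[0]["A"] == pytest.approx(0.5)


def test_ceac_empty_grid_rejected():
    dists = published.cea_arm_distributions("all")
    draws = sc.simulate_psa(dists, n_iter=10, seed=0)
    with pytest.raises(sc.PSAError):
        sc.ceac(draws, np.array([]))


# ---------------------------------------------------------------------------
# Scatterplot
# ---------------------------------------------------------------------------

def test_scatter_all_below_line():
    draws = two_arm_normal_draws((900, 1000), (0, 0), (0.85, 0.80), (0.0, 0.0),
                                 n_iter=20, seed=0)
    points = sc.scatter_points(draws, "A", "B")
    assert sc.fraction_below(points, 50_000.0) == 1.0


def test_scatter_fraction_equals_pairwise_ceac():
    """Definitional identity on the same draws."""
    dists = published.cea_arm_distributions("all")
    draws = sc.simulate_psa(dists, n_iter=4_000, seed=12)
    points = sc.scatter_points(draws, "SCP", "ICBT")
    grid = np.array([0.0, 25_000.0, 50_000.0, 100_000.0])
    pairwise = sc.ceac_pairwise(draws, "SCP", "ICBT", grid)
    for wtp in grid:
        assert sc.fraction_below(points, wtp) == pytest.approx(
            pairwise.loc[wtp], abs=1e-12)


def test_scatter_symmetric_null_near_half():
    draws = two_arm_normal_draws((1000, 1000), (200, 200), (0.8, 0.8),
                                 (0.02, 0.02), n_iter=20_000, seed=14)
    points = sc.scatter_points(draws, "A", "B")
    frac = sc.fraction_below(points, 50_000.0)
    assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 20_000))
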