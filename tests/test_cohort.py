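"""Synthetic cohort generator: calibration, structure, determinism, injections."""

import io

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from dataclasses import replace

import stepcea as sc
from stepcea.cohort import (calibrate_clipped_normal, clipped_normal_moments,
                            clipped_rounded_normal_moments, complement_moments)
from stepcea.cost_tree import COMBO_SECTORS

# ---------------------------------------------------------------------------
# Moment calibration machinery
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("target_mean,target_sd,lo,hi,discrete", [
    (4.61, 5.01, 0, 27, True),     # overall PHQ-9
    (14.67, 3.91, 11, 27, True),   # depressed-stratum PHQ-9
    (2.9, 2.6, 0, 10, True),       # non-depressed-stratum PHQ-9
    (0.86, 0.12, 0.0, 1.0, False),  # EQ-5D with ceiling mass
    (0.66, 0.20, 0.0, 1.0, False),
])
def test_calibration_hits_targets(target_mean, target_sd, lo, hi, discrete):
    """The latent solve reproduces the requested post-clipping moments."""
    mu, sigma = calibrate_clipped_normal(target_mean, target_sd, lo, hi, discrete)
    moments = (clipped_rounded_normal_moments if discrete
               else clipped_normal_moments)
    m, s = moments(mu, sigma, lo, hi)
    assert m == pytest.approx(target_mean, abs=1e-5)
    assert s == pytest.approx(target_sd, abs=1e-3)


def test_calibration_matches_simulation():
    """Analytic clipped moments agree with a direct Monte Carlo draw."""
    mu, sigma = calibrate_clipped_normal(0.86, 0.12, 0.0, 1.0, False)
    rng = np.random.default_rng(0)
    x = np.clip(rng.normal(mu, sigma, 200_000), 0, 1)
    assert x.mean() == pytest.approx(0.86, abs=3 * 0.12 / np.sqrt(200_000))


def test_complement_moments_reconstruct_mixture():
    m, s = complement_moments(0.2, 5.0, 3.0, 10.0, 2.0)
    mix_mean = 0.2 * 10.0 + 0.8 * m
    mix_ex2 = 0.2 * (4.0 + 100.0) + 0.8 * (s**2 + m**2)
    assert mix_mean == pytest.approx(5.0)
    assert mix_ex2 - mix_mean**2 == pytest.approx(9.0)


def test_complement_moments_rejects_incompatible():
    with pytest.raises(sc.ConfigError):
        complement_moments(0.5, 5.0, 0.1, 10.0, 0.1)  # impossible variance


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def test_zero_size_arms_give_empty_cohort():
    cfg = sc.default_cohort_config(seed=1, n_per_arm=0)
    cohort = sc.generate_cohort(cfg)
    assert len(cohort) == 0
    assert list(cohort.columns) == list(sc.cohort.COLUMNS)


def test_seed_determinism_byte_identical():
    cfg = sc.default_cohort_config(seed=42, n_per_arm=150)
    a, b = sc.generate_cohort(cfg), sc.generate_cohort(cfg)
    buf_a, buf_b = io.StringIO(), io.StringIO()
    sc.write_cohort(a, buf_a)
    sc.write_cohort(b, buf_b)
    assert buf_a.getvalue() == buf_b.getvalue()


def test_different_seeds_differ():
    cfg1 = sc.default_cohort_config(seed=1, n_per_arm=100)
    cfg2 = sc.default_cohort_config(seed=2, n_per_arm=100)
    assert not sc.generate_cohort(cfg1).equals(sc.generate_cohort(cfg2))


def test_structural_zero_pattern(small_cohort):
    """No record has positive cost in a sector outside its combination."""
    for combo, sectors in COMBO_SECTORS.items():
        sub = small_cohort[small_cohort.service_combo == combo]
        for sector in ("physician", "outpatient", "inpatient"):
            cols = [f"cost_{sector}_{p}" for p in sc.cohort.PERIODS]
            if sector in sectors:
                assert (sub[cols].sum(axis=1) > 0).all()
            else:
                assert (sub[cols] == 0).all().all()


def test_score_ranges(small_cohort):
    assert small_cohort.phq9_baseline.between(0, 27).all()
    assert small_cohort.eq5d_baseline.between(0, 1).all()
    obs = small_cohort.eq5d_12wk.dropna()
    assert obs.between(0, 1).all()


def test_pooled_calibration_moment_recovery(pooled_cohort_10k):
    """Sample moments at n=10,000 recover the configured pooled targets."""
    c = pooled_cohort_10k
    n = len(c)
    checks = [
        (c.phq9_baseline, 4.61, 5.01),
        (c.phq9_12wk, 3.89, 2.98),
        (c.eq5d_baseline, 0.86, 0.12),
        (c.eq5d_12wk, 0.88, 0.07),
    ]
    for series, mean, sd in checks:
        vals = series.to_numpy(float)
        assert vals.mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(n))
        # se of the sd from the sample fourth moment (non-normal mixtures)
        s2 = vals.var(ddof=1)
        m4 = np.mean((vals - vals.mean()) ** 4)
        se_sd = np.sqrt(max(m4 - s2**2, 0) / n) / (2 * np.sqrt(s2))
        assert vals.std(ddof=1) == pytest.approx(sd, abs=4 * se_sd)


def test_pooled_depressed_fraction(pooled_cohort_10k):
    """The PHQ-9 > 10 share matches the trial's 206/1407 within sampling error."""
    p = 206 / 1407
    n = len(pooled_cohort_10k)
    observed = (pooled_cohort_10k.phq9_baseline > 10).mean()
    assert observed == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / n))


def test_per_arm_service_mix_recovery():
    """SCP combo frequencies at n=100,000 match the configured mix within 3 se."""
    base = sc.default_cohort_config(seed=17, n_per_arm=100_000, missing_rate=0.0,
                                    outlier_rate=0.0)
    scp = [p for p in base.arm_profiles if p.arm_label == "SCP"]
    cohort = sc.generate_cohort(replace(base, arm_profiles=tuple(scp)))
    target = scp[0].service_mix.as_array()
    n = len(cohort)
    counts = cohort.service_combo.value_counts()
    for combo, p in zip(sc.COMBOS, target):
        se = np.sqrt(p * (1 - p) / n)
        assert counts.get(combo, 0) / n == pytest.approx(p, abs=max(3 * se, 1e-12))


def test_phq9_eq5d_negative_correlation(small_cohort):
    r = np.corrcoef(small_cohort.phq9_baseline, small_cohort.eq5d_baseline)[0, 1]
    assert r < -0.3


def test_invalid_profile_errors_name_field():
    cfg = sc.default_cohort_config(seed=0, n_per_arm=10)
    with pytest.raises(sc.ConfigError, match="missing_rate"):
        replace(cfg.arm_profiles[0], missing_rate=1.5)
    with pytest.raises(sc.ConfigError, match="outlier"):
        sc.CohortConfig(arm_profiles=cfg.arm_profiles, outlier_rate=0.1,
                        outlier_multiplier=0.5)


# ---------------------------------------------------------------------------
# Missingness injection
# ---------------------------------------------------------------------------

def test_missingness_rate_zero_is_identity(clean_cohort):
    out = sc.inject_missingness(clean_cohort, 0.0, "MCAR", seed=1)
    pd.testing.assert_frame_equal(out, clean_cohort)


def test_missingness_mcar_rate():
    prof = sc.pooled_arm_profile(n=10_000)
    cohort = sc.generate_cohort(sc.CohortConfig(arm_profiles=(prof,), seed=3))
    out = sc.inject_missingness(cohort, 0.2, "MCAR", seed=7)
    se = np.sqrt(0.2 * 0.8 / len(out))
    assert out.eq5d_12wk.isna().mean() == pytest.approx(0.2, abs=3 * se)
    assert not out.phq9_baseline.isna().any()
    assert not out.eq5d_baseline.isna().any()


def test_missingness_mar_slope_positive():
    """Under MAR, a logistic refit of missingness on baseline PHQ-9 has slope > 0."""
    prof = sc.pooled_arm_profile(n=10_000)
    cohort = sc.generate_cohort(sc.CohortConfig(arm_profiles=(prof,), seed=3))
    out = sc.inject_missingness(cohort, 0.25, "MAR_on_baseline", seed=7)
    miss = out.eq5d_12wk.isna().astype(float)
    X = sm.add_constant(out.phq9_baseline.to_numpy(float))
    res = sm.Logit(miss, X).fit(disp=0)
    slope, slope_se = res.params.iloc[1], res.bse.iloc[1]
    assert slope > 0
    assert slope / slope_se > 3
    se = np.sqrt(0.25 * 0.75 / len(out))
    assert miss.mean() == pytest.approx(0.25, abs=3 * se)


def test_missingness_rate_one_rejected(clean_cohort):
    with pytest.raises(sc.ConfigError):
        sc.inject_missingness(clean_cohort, 1.0, "MCAR", seed=0)


# ---------------------------------------------------------------------------
# Outlier injection
# ---------------------------------------------------------------------------

def test_outliers_rate_zero_is_identity(clean_cohort):
    out = sc.inject_outliers(clean_cohort, 0.0, 10.0, seed=1)
    pd.testing.assert_frame_equal(out, clean_cohort)


def test_outliers_leave_inpatient_untouched(clean_cohort):
    out = sc.inject_outliers(clean_cohort, 0.3, 10.0, seed=1)
    for p in sc.cohort.PERIODS:
        pd.testing.assert_series_equal(out[f"cost_inpatient_{p}"],
                                       clean_cohort[f"cost_inpatient_{p}"])
    assert (out.cost_physician_post.to_numpy()
            != clean_cohort.cost_physician_post.to_numpy()).any()


def test_outliers_trimmed_mean_stable(clean_cohort):
    """Injection at x10 inflates the raw mean; the trimmed mean moves < 1%."""
    out = sc.inject_outliers(clean_cohort, 0.05, 10.0, seed=2)
    col = "cost_physician_post"
    users_before = clean_cohort.loc[clean_cohort[col] > 0, col].to_numpy()
    users_after = out.loc[out[col] > 0, col].to_numpy()
    assert users_after.mean() > 1.2 * users_before.mean()
    trimmed_before, _ = sc.trim_outliers(users_before)
    trimmed_after, _ = sc.trim_outliers(users_after)
    assert trimmed_after.mean() == pytest.approx(trimmed_before.mean(), rel=0.01)


def test_outliers_all_zero_cohort_unchanged(clean_cohort):
    zero = clean_cohort.copy()
    zero[list(sc.cohort.COST_COLUMNS)] = 0.0
    out = sc.inject_outliers(zero, 0.5, 10.0, seed=1)
    pd.testing.assert_frame_equal(out, zero)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def test_csv_round_trip(tmp_path, small_cohort):
    path = tmp_path / "cohort.csv"
    sc.write_cohort(small_cohort, path)
    back = sc.read_cohort(path)
    pd.testing.assert_frame_equal(back, small_cohort, check_dtype=False)
    # missing cells survive as NaN, not zero
    assert back.eq5d_12wk.isna().sum() == small_cohort.eq5d_12wk.isna().sum()
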