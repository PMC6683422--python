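import pytest
from hypothesis import HealthCheck, settings

import stepcea as sc

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """Trial-scale default configuration with missingness and outliers."""
    return sc.default_cohort_config(seed=11, n_per_arm=400,
                                    missing_rate=0.1, outlier_rate=0.02)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sc.generate_cohort(small_config)


@pytest.fixture(scope="session")
def clean_cohort():
    """Fully observed, uncontaminated cohort for classification/adjustment tests."""
    cfg = sc.default_cohort_config(seed=23, n_per_arm=800,
                                   missing_rate=0.0, outlier_rate=0.0)
    return sc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def pooled_cohort_10k():
    """Single pooled-calibration arm, n=10,000, for moment-recovery checks."""
    prof = sc.pooled_arm_profile(n=10_000)
    cfg = sc.CohortConfig(arm_profiles=(prof,), seed=5)
    return sc.generate_cohort(cfg)
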