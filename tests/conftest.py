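import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def validation_cohort():
    """Synthetic case-control cohort tuned to a schizophrenia-like setting.

    Liability-scale target r2 of 0.07 at prevalence 1%, sized like a small
    case-control study; shared across the genome-level tests.
    """
    from embryoscreen.genome import generate_synthetic_cohort

    return generate_synthetic_cohort(
        n_cases=250,
        n_controls=250,
        n_variants=600,
        n_chromosomes=10,
        target_r2_liab=0.07,
        K=0.01,
        seed=20_240,
    )


@pytest.fixture(scope="session")
def validation_pipeline(validation_cohort):
    """End-to-end pipeline run reused by the diagnostic tests."""
    import warnings

    from embryoscreen.genome import run_genome_pipeline

    cohort, gmap, model = validation_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # individuals reused across couples
        return run_genome_pipeline(
            cohort, gmap, model, K=0.01, n_couples=400, n_embryos=10, q=0.02,
            seed=77,
        )


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for Mendelian/IO checks (common disease, fast)."""
    from embryoscreen.genome import generate_synthetic_cohort

    return generate_synthetic_cohort(
        n_cases=30,
        n_controls=30,
        n_variants=60,
        n_chromosomes=6,
        target_r2_liab=0.1,
        K=0.05,
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
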