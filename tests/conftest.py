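import pytest

from fatscreen import (
    GeneratorConfig,
    HydrationTable,
    ObesityScreening,
    generate_cohort,
    generate_lms_fixture,
)


@pytest.fixture(scope="session")
def lms_ref():
    """Monthly-grid fixture reference covering 96-144 months."""
    return generate_lms_fixture()


@pytest.fixture(scope="session")
def coarse_ref():
    """Annual-grid reference, for exercising between-node interpolation."""
    return generate_lms_fixture(step_months=12)


@pytest.fixture(scope="session")
def hydration():
    return HydrationTable.default()


@pytest.fixture(scope="session")
def default_cohort(lms_ref):
    """One default synthetic cohort (n=1400) with its ground-truth ledger."""
    return generate_cohort(GeneratorConfig(), seed=2024, reference=lms_ref)


@pytest.fixture(scope="session")
def fitted(default_cohort, lms_ref):
    cohort, _ = default_cohort
    return ObesityScreening(cohort, lms_ref).fit()


@pytest.fixture(scope="session")
def small_config():
    """Two-centre config for fast pipeline tests."""
    return GeneratorConfig(
        centres={"Alpha": (80, -0.4), "Beta": (80, 0.5)},
    )
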