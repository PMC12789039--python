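import pytest

from apoepaf import fixtures
from apoepaf.synthetic import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def adgc_counts():
    return fixtures.ADGC_COUNTS


@pytest.fixture(scope="session")
def adgc_rrs():
    return fixtures.ADGC_RRS


@pytest.fixture(scope="session")
def a4_counts():
    return fixtures.A4_CARRIER_COUNTS


@pytest.fixture(scope="session")
def medium_cohort():
    """A moderately sized cohort with a common outcome: every genotype
    stratum holds cases, so crude and model-based estimators are all
    defined on it."""
    params = CohortParams(
        n=50_000,
        baseline_risk=0.05,
        genotype_rr={
            "e2/e2": 1.0,
            "e2/e3": 1.5,
            "e3/e3": 2.0,
            "e2/e4": 4.0,
            "e3/e4": 6.0,
            "e4/e4": 10.0,
        },
        seed=7,
    )
    return params, generate_cohort(params)
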