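import pytest
from hypothesis import HealthCheck, settings

import itp_ce as m

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture()
def params():
    """A fresh default base case per test (safe to mutate)."""
    return m.default_base_case()


@pytest.fixture(scope="session")
def life_table():
    return m.synthetic_life_table()


@pytest.fixture(scope="session")
def base_outcomes(life_table):
    """Deterministic base-case outcomes for all three treatments."""
    p = m.default_base_case()
    return {t: m.accumulate_outcomes(m.run_cohort(p, t, life_table), p, t)
            for t in m.TREATMENTS}


def short_horizon(p, years=10.0):
    """Truncate the horizon for fast model runs in structural tests."""
    p.settings.max_age = p.demography.mean_age + years
    return p
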