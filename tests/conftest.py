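import pytest
from hypothesis import HealthCheck, settings

import mshap

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_fixture():
    return mshap.generate_worked_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    return mshap.generate_cohort(mshap.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_bounds_table():
    bounds = mshap.default_bounds()
    return bounds, mshap.bounds_table_from_frame(bounds)
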