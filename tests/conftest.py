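import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from evadx import simulate  # noqa: E402
from evadx.genemodel import FIXTURE_TAG, load_transcript  # noqa: E402


@pytest.fixture(scope="session")
def model():
    return load_transcript(FIXTURE_TAG)


@pytest.fixture(scope="session")
def genome(model):
    return simulate.simulate_reference(0, model)


@pytest.fixture(scope="session")
def panel(model):
    return simulate.default_panel(model)


@pytest.fixture(scope="session")
def table2_cohort(panel):
    spec = simulate.table2_cohort_spec(panel, seed=17)
    dm, truth = simulate.simulate_depth_matrix(spec)
    return spec, dm, truth
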