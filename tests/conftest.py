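import pytest
from hypothesis import HealthCheck, settings

from vlucea.synthetic import generate_baseline_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    """Baseline parameter bundle with synthetic jurisdiction profiles."""
    return generate_baseline_bundle(seed=0)


@pytest.fixture(scope="session")
def aggregate(bundle):
    return bundle.jurisdiction("AGGREGATE")
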