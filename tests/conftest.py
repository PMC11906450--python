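import pytest
from hypothesis import HealthCheck, settings

from mitochar.simulate import default_test_suite_spec, fixture_annotation, generate_genome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tabaci():
    return fixture_annotation("tabaci")


@pytest.fixture(scope="session")
def parvispinus():
    return fixture_annotation("parvispinus")


@pytest.fixture(scope="session")
def suite():
    """Default synthetic genome: (spec, sequence, annotation, manifest)."""
    spec = default_test_suite_spec(seed=1)
    sequence, annotation = generate_genome(spec)
    return spec, sequence, annotation, spec.manifest()
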