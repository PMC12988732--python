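import pytest
from hypothesis import HealthCheck, settings

from eggrisk.data_io import example_reference_path, read_reference_tables
from eggrisk.synthetic_data import GeneratorConfig, generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference():
    """(profiles, toxicity, limits) from the packaged example YAML."""
    return read_reference_tables(example_reference_path())


@pytest.fixture(scope="session")
def profiles(reference):
    return reference[0]


@pytest.fixture(scope="session")
def toxicity(reference):
    return reference[1]


@pytest.fixture(scope="session")
def limits(reference):
    return reference[2]


@pytest.fixture(scope="session")
def default_records():
    """Default nine-area synthetic dataset (seed 1): 900 records."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def profile_map(profiles):
    return {p.group: p for p in profiles}
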