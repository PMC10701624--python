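import pytest
from hypothesis import HealthCheck, settings

from accipiter.cohort import assign_population_groups
from accipiter.synthetic import default_config, generate_population

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_table():
    """One study-condition synthetic table with population groups assigned."""
    cfg = default_config(seed=42)
    return assign_population_groups(generate_population(cfg))


@pytest.fixture(scope="session")
def study_config():
    return default_config(seed=42)
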