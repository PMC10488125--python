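import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from dustrisk.synthetic import GeneratorConfig, generate_study  # noqa: E402


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def bundle(default_config):
    """One seeded synthetic study shared across read-only tests."""
    return generate_study(default_config)


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Zero analytical noise: every closed-form identity holds exactly."""
    return generate_study(GeneratorConfig(seed=3, noise_sigma=0.0))
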