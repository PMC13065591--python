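import pytest

from ventrecon import build_episodes
from ventrecon.synthetic import ScenarioConfig, generate_cohort


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Small fully documented, zero-jitter cohort with its ground truth."""
    cfg = ScenarioConfig.noise_free(n_patients=60, seed=3)
    truth, tables = generate_cohort(cfg)
    return truth, tables


@pytest.fixture(scope="session")
def noise_free_build(noise_free_cohort):
    truth, tables = noise_free_cohort
    return truth, build_episodes(tables)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-noise cohort large enough for rate checks."""
    cfg = ScenarioConfig(n_patients=800, seed=11)
    truth, tables = generate_cohort(cfg)
    return truth, tables


@pytest.fixture(scope="session")
def noisy_build(noisy_cohort):
    truth, tables = noisy_cohort
    return truth, build_episodes(tables)
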