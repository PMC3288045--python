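import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from g1screen import RunConfig, SimulationConfig, analyze_screen, simulate_screen
from g1screen.config import reference_hits

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_planted_config():
    """100-target screen with 3 hits per grade, full per-cell simulation."""
    cfg = SimulationConfig(seed=11, n_targets=100)
    cfg.planted_hits = reference_hits(cfg, 3, 3, 3)
    return cfg


@pytest.fixture(scope="session")
def small_screen(small_planted_config):
    return simulate_screen(small_planted_config)


@pytest.fixture(scope="session")
def small_analysis(small_planted_config, small_screen):
    run_cfg = RunConfig(seed=11, simulation=small_planted_config)
    return analyze_screen(small_screen, run_cfg)
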