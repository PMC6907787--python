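import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from vaxbiome import simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Reduced study for fast tests: same shape, fewer OTUs and mice."""
    return simulate.SimConfig(
        seed=7,
        n_otus=80,
        mice_per_group={"NG": 3, "WT": 3, "MPER": 3, "IL1b": 3, "FliC": 3, "RB": 3},
        mean_depth=5000,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate.simulate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    cfg = simulate.SimConfig(seed=42)
    return cfg, simulate.simulate_study(cfg)
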