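import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """Baseline parameters over a reduced base population (fast replicates)."""
    from nipt_bia import default_config

    cfg = default_config()
    cfg.population.base_population_total = 120_000
    cfg.population.prevalence_scale = 5.0  # enough affected pregnancies at this scale
    return cfg
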