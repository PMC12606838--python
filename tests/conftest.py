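import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def region_rows():
    """Default synthetic estimation table plus its noise-free truth."""
    from dfps import GeneratorConfig, gen_region_rows

    return gen_region_rows(GeneratorConfig(seed=20240901))


@pytest.fixture(scope="session")
def noise_free_rows():
    from dfps import GeneratorConfig, gen_region_rows

    cfg = GeneratorConfig(seed=7, logit_noise_sd=0.0, country_effect_sd=0.0)
    return gen_region_rows(cfg)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
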