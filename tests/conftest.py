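import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tumorclock as tc

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mx34():
    """Colorectal patient with rate curve mu(t) = 2e-5 * exp(0.0032 t)."""
    return tc.MX34_PARAMS


@pytest.fixture(scope="session")
def co82():
    """Colorectal patient with s=0.0075, a=0.309, mu0=2e-7."""
    return tc.CO82_PARAMS


@pytest.fixture(scope="session")
def five_stage_defs():
    """Stage map used for 5-observation recovery experiments."""
    return tc.StageDefinition.from_mapping(
        {
            "microadenoma": 3,
            "small_adenoma": 4,
            "large_adenoma": 5,
            "early_carcinoma": 8,
            "carcinoma": 12,
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
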