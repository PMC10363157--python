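import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import uaod_kinetics as uk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TIMES = np.arange(0.0, 81.0, 10.0)


@pytest.fixture(scope="session")
def times():
    return TIMES.copy()


@pytest.fixture(scope="session")
def noiseless_study():
    """Default 3x3x3 study with zero noise: MR is exactly the Page curve."""
    design = uk.StudyDesign(seed=0, noise_sd=0.0, sg_noise_sd_pct=0.0)
    return uk.simulate_study(design)


@pytest.fixture(scope="session")
def noisy_study():
    """Default study at the design noise level (sigma = 0.005 MR units)."""
    return uk.simulate_study(uk.StudyDesign(seed=11))
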