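import numpy as np
import pytest

from stridetrends import GaitTrialSpec, generate_gait_trial


@pytest.fixture(scope="session")
def default_trial():
    """One synthetic trial at the default study conditions."""
    return generate_gait_trial(GaitTrialSpec(seed=11))


@pytest.fixture(scope="session")
def quiet_trial():
    """Low-noise trial for trend-recovery checks."""
    return generate_gait_trial(GaitTrialSpec(residual_cv=0.003, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
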