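import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aclscreen.orientation import calibrate_static, estimate_orientation
from aclscreen.simulate import TrialBlueprint, simulate_mcmj_trial, simulate_sls_trial

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mcmj_trial():
    """Default five-rep jump trial with gate and ground truth (seed 1)."""
    bp = TrialBlueprint(task="mcmj", seed=1)
    trial, gate, truth = simulate_mcmj_trial(bp)
    return bp, trial, gate, truth


@pytest.fixture(scope="session")
def mcmj_oriented(mcmj_trial):
    """Calibrated orientation series for the default jump trial."""
    _, trial, _, _ = mcmj_trial
    cal = calibrate_static(trial, (0.0, 10.0))
    return cal, estimate_orientation(trial, cal)


@pytest.fixture(scope="session")
def sls_trial():
    """Default five-rep squat trial with ground truth (seed 3)."""
    bp = TrialBlueprint(task="sls", seed=3)
    trial, truth = simulate_sls_trial(bp)
    return bp, trial, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
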