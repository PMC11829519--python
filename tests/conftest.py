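import numpy as np
import pytest

from limbpoint.limb_model import Anthropometrics, LimbModel
from limbpoint.protocol import make_target
from limbpoint.synthetic import make_profile, simulate_trial

#: Control-group mean active ROM (deg) used for reference targets.
CONTROL_ROM = {"hip": 64.7, "knee": 103.1, "ankle": 17.1}


@pytest.fixture(scope="session")
def model() -> LimbModel:
    """Reference limb scaled from a 71 kg, 1.70 m body."""
    return LimbModel(anthropometrics=Anthropometrics.from_body(71.0, 1.70))


@pytest.fixture(scope="session")
def control_profile():
    rng = np.random.default_rng(11)
    return make_profile("C01", "control", rng)


@pytest.fixture(scope="session")
def sci_profile():
    rng = np.random.default_rng(12)
    return make_profile("S01", "SCI", rng, rho=1.5)


@pytest.fixture(scope="session")
def hka_target(model):
    return make_target(model, np.zeros(3), CONTROL_ROM, frozenset({"hip", "knee", "ankle"}))


@pytest.fixture(scope="session")
def noiseless_trial(control_profile, model, hka_target):
    """One undistorted, noise-free simulated trial with a fixed 0.6 s out phase."""
    profile = control_profile
    undistorted = type(profile)(
        pid=profile.pid, group=profile.group,
        anthropometrics=model.anthropometrics, rom_deg=CONTROL_ROM,
        rho=0.0, distortions={},
    )
    target = make_target(model, np.zeros(3), CONTROL_ROM, frozenset({"hip", "knee", "ankle"}))
    return simulate_trial(undistorted, target, seed=1234, out_duration=0.6,
                          marker_noise_sd=0.0)
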