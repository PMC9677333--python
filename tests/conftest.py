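import numpy as np
import pytest

from protonrad import (
    AcquisitionParams,
    LandmarkPairs,
    Radiograph,
    make_collimator_radiograph,
    make_mouse_pair,
)


@pytest.fixture(scope="session")
def mouse_pair():
    """Shared synthetic plan/radiograph pair with a known transform."""
    return make_mouse_pair(seed=42, true_transform=(1.0, 5.0, (10.0, -6.0)))


@pytest.fixture(scope="session")
def mouse_landmarks(mouse_pair):
    truth = mouse_pair["ground_truth"].truth
    return LandmarkPairs(
        np.asarray(truth["plan_landmarks"]), np.asarray(truth["radio_landmarks"])
    )


@pytest.fixture(scope="session")
def collimator_noiseless():
    acq = AcquisitionParams(n_frames=1, poisson_noise=False, seed=None)
    stack, gt = make_collimator_radiograph((120.0, 132.5), 3.0, acq)
    return stack, gt


@pytest.fixture()
def flat_radiograph():
    return Radiograph(np.full((40, 40), 100.0), pixel_pitch_mm=0.05)
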