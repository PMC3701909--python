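import logging

import numpy as np
import pytest

from smkin import AcquisitionMeta, SimKineticParams

# the rendered-field clipping warning is expected whenever free molecules
# wander past the field edge; keep test output readable
logging.getLogger("smkin.sim").setLevel(logging.ERROR)


@pytest.fixture
def fast_meta():
    """Short-exposure acquisition: every molecule resolved."""
    return AcquisitionMeta(frame_interval=0.0175, exposure_time=0.0175,
                           field_size=(64, 64), n_frames=200)


@pytest.fixture
def timelapse_meta():
    """0.1 s time-lapse with 50 ms exposure, 10 um field."""
    return AcquisitionMeta(frame_interval=0.1, exposure_time=0.05,
                           field_size=(96, 96), n_frames=600)


@pytest.fixture
def two_state_params():
    """Off time 5.2 s against a 30 s bleach standard."""
    return SimKineticParams(k_off=1 / 5.2, k_bl=1 / 30.0, k_bind=0.5)


def rayleigh_mean_sq_se(mean_sq: float, n: int) -> float:
    """SE of the mean squared 2D Brownian step (exponentially distributed)."""
    return mean_sq / np.sqrt(n)
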