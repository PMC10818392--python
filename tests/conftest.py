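import numpy as np
import pytest

from posturokit import BoardRecording, CoPTrajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240351)


@pytest.fixture
def random_trajectory(rng):
    """A 50-sample random CoP trajectory at 20 Hz."""
    return CoPTrajectory(
        rate=20.0,
        cp_ap=rng.normal(0, 2, size=50),
        cp_ml=rng.normal(0, 2, size=50),
    )


def make_trajectory(ap, ml, rate=20.0):
    return CoPTrajectory(rate=rate, cp_ap=np.asarray(ap, float),
                         cp_ml=np.asarray(ml, float))


@pytest.fixture
def regular_recording():
    """A 3-second regular 20 Hz recording with smooth channels."""
    t = np.arange(61) / 20.0
    return BoardRecording(
        timestamps=t,
        fl=25 + np.sin(t),
        fr=25 + np.cos(t),
        pl=25 - 0.5 * np.sin(t),
        pr=25 + 0.2 * t,
        board_id="fixture",
    )
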