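import numpy as np
import pytest

import flowmrd as fm


@pytest.fixture
def small_matrix() -> fm.EventMatrix:
    return fm.EventMatrix(
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.5]]),
        channels=[fm.ChannelInfo("FSC"), fm.ChannelInfo("SSC", stain_name="side")],
        specimen_id="small",
    )


@pytest.fixture(scope="session")
def separable_training() -> fm.TrainingSet:
    """Two well-separated point clouds in [-1, 1]^3, already scaled."""
    rng = np.random.default_rng(42)
    n = 300
    lo = rng.normal(-0.5, 0.08, (n, 3))
    hi = rng.normal(0.5, 0.08, (n, 3))
    return fm.TrainingSet(
        features=np.vstack([hi, lo]),
        flags=np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)],
        sources=np.array(["blasts"] * n + ["donor"] * n, dtype=object),
        channels=["a", "b", "c"],
    )


@pytest.fixture(scope="session")
def tiny_patient():
    """A small synthetic patient (blasts + 3 donors) for pipeline tests."""
    blasts, donors = fm.synthetic_patient(5, n_blast=1500, n_donors=3,
                                          donor_events=1500)
    return blasts, donors
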