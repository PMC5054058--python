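import numpy as np
import pytest

from addhrvr import (
    CalibrationSession,
    EpochSeries,
    Phase,
    SimConfig,
    fit_inverse_model,
    simulate_calibration,
)


@pytest.fixture
def sim_cfg():
    return SimConfig()


@pytest.fixture
def good_session(sim_cfg):
    return simulate_calibration(sim_cfg, person_seed=42, person_id="p042")


@pytest.fixture
def good_model(good_session):
    model = fit_inverse_model(good_session)
    assert model.ok
    return model


def make_session(rmssd, accel, person_id="t", epoch_length=30.0, phases=None):
    """Build a calibration session from raw epoch arrays, rest phase first."""
    rmssd = np.asarray(rmssd, dtype=float)
    accel = np.asarray(accel, dtype=float)
    n = rmssd.size
    starts = np.arange(n) * epoch_length
    epochs = EpochSeries(person_id, starts, rmssd, accel, epoch_length=epoch_length)
    if phases is None:
        phases = [Phase("rest", 0.0, n * epoch_length)]
    return CalibrationSession(person_id, phases, epochs)
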