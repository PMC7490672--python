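import numpy as np
import pytest

from accelcal.cutpoints import BUTTE_HIP, label_series
from accelcal.simulate import (
    ActivityStateModel,
    CountEmissionModel,
    emit_counts,
    simulate_states,
)
from accelcal.util import round_half_up


@pytest.fixture(scope="session")
def sticky_model():
    return ActivityStateModel.sticky()


@pytest.fixture(scope="session")
def pure_training_data(sticky_model):
    """Noise-free calibration table: wrist = round(3.2 x hip cpm), Butte labels.

    Pure emission keeps each state's counts strictly inside its Butte
    interval, so the hip labels equal the simulated states exactly.
    """
    rng = np.random.default_rng(42)
    states = simulate_states(sticky_model, 20000, rng)
    emission = CountEmissionModel(pure=True, noise_sigma=0.0)
    hip, _ = emit_counts(states, emission, rng)
    hip_cpm = hip * 4
    labels = label_series(hip_cpm, BUTTE_HIP)
    wrist_cpm = round_half_up(3.2 * hip_cpm).astype(np.int64)
    return wrist_cpm, labels


@pytest.fixture(scope="session")
def noisy_training_data(sticky_model):
    """Calibration table under the simulator's default emission and noise."""
    rng = np.random.default_rng(7)
    states = simulate_states(sticky_model, 20000, rng)
    hip, wrist = emit_counts(states, CountEmissionModel(), rng)
    hip_cpm, wrist_cpm = hip * 4, wrist * 4
    return wrist_cpm, label_series(hip_cpm, BUTTE_HIP)
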