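import numpy as np
import pytest

from pulsefed import gan
from pulsefed.simulate import PerSegmentVariation, SimParams, make_dataset

# Small-geometry specs: 40-sample segments at 25 Hz (1.6 s, ~2 beats at 75
# bpm) keep LSTM/conv shapes realistic while running in milliseconds.
SMALL_LEN = 40


@pytest.fixture(scope="session")
def small_gen_spec():
    return gan.GeneratorSpec(num_layers=2, hidden_units=6,
                             input_len=SMALL_LEN, output_len=SMALL_LEN)


@pytest.fixture(scope="session")
def small_disc_spec():
    return gan.DiscriminatorSpec(input_len=SMALL_LEN, channels=(3, 4, 5, 6), kernel=3)


@pytest.fixture(scope="session")
def small_sim_params():
    return SimParams(hr_bpm=75.0, fs_hz=25.0, seg_len_samples=SMALL_LEN,
                     noise_sd=0.0, drift_amp=0.0, seed=11)


@pytest.fixture(scope="session")
def small_pairs(small_sim_params):
    return make_dataset(small_sim_params, 24,
                        PerSegmentVariation(sbp_sd=4.0, dbp_sd=3.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
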