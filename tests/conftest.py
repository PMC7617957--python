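import numpy as np
import pytest

from barrelcircuit import synthdata as sd


@pytest.fixture(scope="session")
def barrel_scene():
    """A mid-size noisy barrel scene shared across histology tests."""
    return sd.gen_barrel_image(sd.BarrelImageParams(seed=11, noise_sd=400.0))


@pytest.fixture(scope="session")
def small_ephys_session():
    params = sd.EphysSimParams(
        n_units=6, trials_per_whisker=30, p_pw=0.6, p_aw=0.3,
        spont_rate=2.0, n_light_trials=25, untagged_latency_mean=8.0,
        seed=7,
    )
    return sd.gen_ephys_session(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
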