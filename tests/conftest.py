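import numpy as np
import pytest

from mbflex.synth import (
    KcSynthConfig,
    MBON_STIMULI,
    MbonSynthConfig,
    gen_kc_dataset,
    gen_mbon_dataset,
    make_schedule,
)


@pytest.fixture(scope="session")
def small_kc():
    """A modest KC dataset shared by imaging/decoding tests."""
    cfg = KcSynthConfig(n_cells=120, n_trials_per_stim=4, seed=5)
    tensor, schedule, gt = gen_kc_dataset(cfg)
    return cfg, tensor, schedule, gt


@pytest.fixture(scope="session")
def mbon_schedule():
    return make_schedule(MBON_STIMULI, 2, 10.0, 5.0)


@pytest.fixture(scope="session")
def mbon_clean(mbon_schedule):
    """Noise-free MBON dataset with depression 0.3 / recovery 1.0."""
    cfg = MbonSynthConfig(noise_sd=0.0, seed=3)
    pre, post, gt = gen_mbon_dataset(cfg, mbon_schedule)
    return cfg, pre, post, gt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
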