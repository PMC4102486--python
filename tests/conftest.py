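import numpy as np
import pytest

import nirsvig as nv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def behavior_cfg():
    return nv.BehaviorConfig()


@pytest.fixture(scope="session")
def channels():
    return nv.make_channel_table()


@pytest.fixture(scope="session")
def small_session():
    """A small but complete simulated subject: 3 runs x 20 trials.

    Deterministic (fixed master seed); strong RT coupling and iid trialwise
    vigilance so decoding signal is present without trial-to-trial carryover.
    """
    beh = nv.BehaviorConfig(n_runs=3, n_trials_per_run=20)
    beh.vigilance.ar_coef = 0.0
    sig = nv.SignalConfig(coupling_beta=0.005)
    cfg = nv.PipelineConfig(behavior=beh, signal=sig, n_subjects=2,
                            master_seed=77)
    data = nv.simulate_subject(cfg, 0)
    chromo, chromo_norm = nv.preprocess_subject(data, cfg.filter)
    return cfg, data, chromo, chromo_norm


@pytest.fixture
def narrow_windows():
    """Reduced sliding-window range for fast decoding tests."""
    return nv.WindowSpec(start_time=-2.0, end_time=9.0, width=7, step=6)
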