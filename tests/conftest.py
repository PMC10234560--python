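import numpy as np
import pytest

from stnadapt import (
    AgentConfig,
    LfpGenConfig,
    StimScheduleConfig,
    TaskConfig,
    simulate_session,
)

# Scaled study conditions used throughout the suite: one hemisphere,
# 60 trials, 400 Hz native rate.  Full-size defaults (16 subjects,
# 100 trials, 2048 Hz, 2 hemispheres) are exercised where the test needs
# them (artifact removal runs at the native 2048 Hz).
SCALED_RATE = 400.0


@pytest.fixture(scope="session")
def scaled_lfp_cfg():
    return LfpGenConfig(rate=SCALED_RATE)


@pytest.fixture(scope="session")
def coupled_session(scaled_lfp_cfg):
    """One scaled session with all couplings at their defaults."""
    return simulate_session(
        "sub-01", TaskConfig(n_trials=60), AgentConfig(), scaled_lfp_cfg,
        n_hemispheres=1, seed=42,
    )


@pytest.fixture(scope="session")
def stim_pair():
    """Contaminated stimulation session and its artifact-free twin at the
    native 2048 Hz (identical seeds, schedules, and beta suppression)."""
    from dataclasses import replace

    task, agent = TaskConfig(n_trials=60), AgentConfig()
    lfp = LfpGenConfig()
    stim = StimScheduleConfig()
    contaminated = simulate_session(
        "sub-01", task, agent, lfp, stim_cfg=stim, n_hemispheres=1, seed=7
    )
    twin = simulate_session(
        "sub-01", task, agent, replace(lfp, artifact_amplitude=0.0),
        stim_cfg=stim, n_hemispheres=1, seed=7,
    )
    return contaminated, twin


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
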