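import math

import numpy as np
import pytest

from betalearn.synth import AgentConfig, BurstSignalConfig, gen_agent_performance, gen_burst_signal


@pytest.fixture(scope="session")
def agent_output():
    """A 120-trial agent run shared across tests."""
    cfg = AgentConfig(
        beta0=0.0, beta1=-0.1, beta2=0.1, zeta=1e-6,
        n_trials=120, cv_init=0.5, omega2=-4.0,
        omega1=-3.0, pi_u=math.exp(3.0), seed=11,
    )
    return gen_agent_performance(cfg)


@pytest.fixture(scope="session")
def burst_signal():
    cfg = BurstSignalConfig(
        fs=256.0, duration_s=60.0, burst_rate_per_s=0.4,
        burst_amplitude=6.0, noise_amplitude=1.0, seed=5,
    )
    return gen_burst_signal(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
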