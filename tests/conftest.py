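import numpy as np
import pytest

from arbrl.params import ModelParams
from arbrl.task import make_block_spec, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def control_params():
    """Control-like dynamic omega-rho agent at the canonical simulation values."""
    return ModelParams(
        alpha_pos=0.5, alpha_neg=0.5, zeta=0.3, beta1=8.0, beta0=0.0,
        omega0=0.374, alpha_omega=0.2, zeta_omega=0.05, rho=0.5,
    )


@pytest.fixture
def stim_learner_params():
    return ModelParams(alpha_pos=0.6, alpha_neg=0.3, zeta=0.2, beta1=10.0, beta0=0.0)


@pytest.fixture
def small_session(control_params):
    """A 10-block what/where session simulated by the control-like agent."""
    rng = np.random.default_rng(7)
    blocks = [make_block_spec("what_where", rng) for _ in range(10)]
    sess, trajs = simulate_session("dynamic_omega_rho", control_params, blocks, rng)
    return sess, trajs
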