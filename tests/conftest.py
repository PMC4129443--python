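import numpy as np
import pytest

from revlearn import AgentParams, TaskConfig, simulate_session


@pytest.fixture
def cfg():
    """The default human-style task: 160 trials, 70:30, reversal after 80."""
    return TaskConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240812)


@pytest.fixture
def hybrid_session(cfg):
    """One simulated hybrid session with full latent traces."""
    params = AgentParams(alpha0=0.3, beta=5.0, eta=0.3)
    return simulate_session(params, cfg, np.random.default_rng(7))


def random_params(rng, hybrid=True):
    """Uniform draw of valid agent parameters (beta kept moderate)."""
    return AgentParams(
        alpha0=float(rng.random()),
        beta=float(rng.random() * 10.0),
        eta=float(rng.random()) if hybrid else 0.0,
    )
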