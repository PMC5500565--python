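import numpy as np
import pytest

from rpemap import rl, synth, task


@pytest.fixture(scope="session")
def small_session():
    """A 2x60-trial softmax-agent session with its generating latents."""
    cfg = task.TaskConfig(n_blocks=2, trials_per_block=60, seed=11)
    params = rl.RLParams(alpha=0.3, beta=5.0, phi=0.0)
    session, trace = synth.gen_behavior(params, cfg, np.random.default_rng(11))
    return session, trace, params


@pytest.fixture(scope="session")
def default_session():
    """Full-size (2x170) session from the softmax agent."""
    cfg = task.TaskConfig(seed=7)
    params = rl.RLParams(alpha=0.3, beta=5.0, phi=0.0)
    session, trace = synth.gen_behavior(params, cfg, np.random.default_rng(7))
    return session, trace, params
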