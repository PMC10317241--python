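import numpy as np
import pytest

from scoin import AgentConfig, Block, TaskConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_context_task():
    """Generic curl-force task: baseline plus one 4-unit adaptation."""
    return TaskConfig(
        context_adaptations=(0.0, 4.0),
        adaptation_noise=1.0,
        observation_noise=0.1,
        blocks=(Block(1, 20), Block(0, 10)),
        cues_present=True,
        cue_uncertainty=0.0,
    )


@pytest.fixture
def two_context_agent():
    return AgentConfig(
        p_self=0.9,
        sigma_r=0.5,
        sigma_u=0.17,
        eta=0.0,
        hyperpriors=((0.0, 1e4, 33e3, 1e5), (0.0, 1.0, 4e2, 23e2)),
    )
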