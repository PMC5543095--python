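import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from revcat.agent import ModelConfig, enumerate_strategies, init_agent
from revcat.task import build_session


@pytest.fixture(scope="session")
def session_one():
    return build_session(1)


@pytest.fixture()
def config():
    return ModelConfig(first_count=3, second_count=6, finst_span_s=100.0)


@pytest.fixture()
def agent(config):
    return init_agent(config, seed=12345)


def make_agent_with(conditions, response, config, seed=0, **strategy_fields):
    """Agent whose current strategy is the given one, with fields overridden."""
    state = init_agent(config, seed=seed)
    strategy = state.store.find(tuple(sorted(conditions)), response)
    for name, value in strategy_fields.items():
        setattr(strategy, name, value)
    state.store.note_retrieval(strategy, state.clock)
    state.current = strategy
    return state
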