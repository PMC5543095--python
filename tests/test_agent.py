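"""Agent: strategy store, matching, feedback processing, retrieval, switching."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import make_agent_with
from revcat.agent import (
    LEVEL_ONE,
    LEVEL_TWO,
    ModelConfig,
    Strategy,
    choose_response,
    config_from_label,
    default_grid,
    enumerate_strategies,
    init_agent,
    matches,
    process_negative,
    process_positive,
    retrieve,
)
from revcat.task import Tone, enumerate_tones


def S(conds, response, **kw):
    return Strategy(tuple(sorted(conds)), response, **kw)


class TestStore:
    def test_enumeration_counts(self):
        store = enumerate_strategies()
        assert len(store.strategies) == 64
        assert len(store.one_feature()) == 16
        assert len(store.two_feature()) == 48

    def test_all_distinct_and_fresh(self):
        store = enumerate_strategies()
        keys = {s.matches_key() for s in store.strategies}
        assert len(keys) == 64
        assert all(
            s.success_count == 0
            and not s.often_successful
            and not s.failed
            and s.last_retrieved_at is None
            for s in store.strategies
        )

    def test_two_feature_conditions_use_distinct_features(self):
        store = enumerate_strategies()
        for s in store.two_feature():
            assert len({f for f, _ in s.conditions}) == 2


@pytest.mark.parametrize(
    "conds, response, tone, expected",
    [
        ([("intensity", "high")], 1, Tone("short", "rising", "high", "low"), 1),
        ([("duration", "short")], 1, Tone("long", "rising", "high", "low"), 0),
        ([("duration", "short")], 0, Tone("long", "rising", "high", "low"), 1),
        ([("duration", "short")], 1, Tone("short", "rising", "high", "low"), 1),
        (
            [("duration", "short"), ("direction", "rising")],
            1,
            Tone("short", "falling", "high", "low"),
            0,
        ),
        (
            [("duration", "short"), ("direction", "rising")],
            1,
            Tone("short", "rising", "low", "high"),
            1,
        ),
    ],
)
def test_choose_response_react_same_or_different(conds, response, tone, expected):
    assert choose_response(S(conds, response), tone) == expected


@given(tone_index=st.integers(0, 15), strategy_index=st.integers(0, 63))
def test_response_is_binary_and_consistent_with_matching(tone_index, strategy_index):
    tone = enumerate_tones()[tone_index]
    strategy = enumerate_strategies().strategies[strategy_index]
    response = choose_response(strategy, tone)
    assert response in (0, 1)
    assert (response == strategy.response) == matches(strategy, tone)


class TestProcessPositive:
    def test_count_increments_to_threshold(self, config):
        state = make_agent_with([("duration", "short")], 1, config, success_count=2)
        process_positive(state, config)
        assert state.current.success_count == 3
        assert state.current.often_successful

    def test_count_caps_at_threshold(self, config):
        state = make_agent_with(
            [("duration", "short")], 1, config, success_count=3, often_successful=True
        )
        process_positive(state, config)
        assert state.current.success_count == 3

    def test_two_feature_threshold_is_second_count(self, config):
        state = make_agent_with(
            [("duration", "short"), ("direction", "rising")], 1, config, success_count=5
        )
        process_positive(state, config)
        assert state.current.often_successful

    def test_success_clears_error_flag(self, config):
        state = make_agent_with(
            [("duration", "short")], 1, config, success_count=3, often_successful=True
        )
        state.control.error_noted = True
        process_positive(state, config)
        assert not state.control.error_noted


class TestProcessNegative:
    def test_often_successful_gets_reevaluated_first(self, config):
        state = make_agent_with(
            [("duration", "short")], 1, config, success_count=3, often_successful=True
        )
        kept = state.current
        process_negative(state, config)
        assert state.current is kept
        assert state.control.error_noted
        assert not kept.failed

    def test_repeated_failure_of_one_feature_switches_level(self, config):
        state = make_agent_with(
            [("duration", "short")], 1, config, success_count=3, often_successful=True
        )
        state.control.error_noted = True
        process_negative(state, config)
        assert state.control.level == LEVEL_TWO
        assert state.current.complexity == 2
        assert not state.control.error_noted

    def test_repeated_failure_of_two_feature_flags_env_change(self, config):
        state = make_agent_with(
            [("duration", "short"), ("direction", "rising")],
            1,
            config,
            success_count=6,
            often_successful=True,
        )
        state.control.level = LEVEL_TWO
        state.control.error_noted = True
        old = state.current
        process_negative(state, config)
        assert state.control.env_change
        assert old.failed
        assert state.current is not old
        assert state.current.complexity == 2

    def test_immediate_failure_flips_response(self, config):
        state = make_agent_with([("intensity", "high")], 1, config, success_count=0)
        process_negative(state, config)
        assert state.current.conditions == (("intensity", "high"),)
        assert state.current.response == 0

    def test_partial_success_changes_pair_keeps_response(self, config):
        state = make_agent_with([("intensity", "high")], 1, config, success_count=1)
        old = state.current
        process_negative(state, config)
        assert old.failed
        assert state.current.complexity == 1
        assert state.current.response == old.response
        assert state.current.conditions != old.conditions

    def test_exhausted_one_feature_pool_forces_level_switch(self, config):
        state = make_agent_with([("intensity", "high")], 1, config, success_count=1)
        for s in state.store.one_feature():
            if s is not state.current:
                s.failed = True
        process_negative(state, config)
        assert state.control.level == LEVEL_TWO
        assert state.current.complexity == 2

    def test_two_feature_immediate_failure_switches_anywhere(self, config):
        state = make_agent_with(
            [("duration", "short"), ("direction", "rising")], 1, config, success_count=0
        )
        state.control.level = LEVEL_TWO
        old = state.current
        process_negative(state, config)
        assert old.failed
        assert state.current is not old
        assert state.current.complexity == 2

    def test_two_feature_partial_success_keeps_a_condition_and_response(self, config):
        state = make_agent_with(
            [("duration", "short"), ("direction", "rising")], 1, config, success_count=2
        )
        state.control.level = LEVEL_TWO
        old = state.current
        process_negative(state, config)
        new = state.current
        assert new.response == old.response
        assert len(set(new.conditions) & set(old.conditions)) == 1


class TestRetrieve:
    def test_recent_strategy_excluded_until_window_expires(self, config):
        store = enumerate_strategies()
        rng = np.random.default_rng(0)
        cfg80 = ModelConfig(finst_span_s=80.0)
        target = store.one_feature()[0]
        store.note_retrieval(target, 100.0)
        for s in store.one_feature():
            if s is not target:
                s.failed = True
        # retrieved 50 s ago with an 80 s window: ineligible
        assert retrieve(store, now=150.0, config=cfg80, rng=rng, complexity=1) is None
        # 120 s ago with a 100 s window: eligible again
        cfg100 = ModelConfig(finst_span_s=100.0)
        got = retrieve(store, now=220.0, config=cfg100, rng=rng, complexity=1)
        assert got is target

    def test_seeded_determinism(self, config):
        picks = []
        for _ in range(2):
            store = enumerate_strategies()
            rng = np.random.default_rng(99)
            s = retrieve(store, now=0.0, config=config, rng=rng, complexity=1)
            picks.append(s.matches_key())
        assert picks[0] == picks[1]

    def test_empty_set_is_signalled(self, config):
        store = enumerate_strategies()
        for s in store.one_feature():
            s.failed = True
        got = retrieve(
            store, now=0.0, config=config, rng=np.random.default_rng(0), complexity=1
        )
        assert got is None

    def test_bounded_recency_pool_forgets_older_uses(self):
        cfg = ModelConfig(num_finsts=2)
        store = enumerate_strategies()
        ones = store.one_feature()
        for i, s in enumerate(ones[:3]):
            store.note_retrieval(s, float(i))
        recent = store.recently_retrieved_ids(3.0, cfg)
        assert id(ones[0]) not in recent  # evicted from the 2-slot pool
        assert {id(ones[1]), id(ones[2])} <= recent


class TestInitAgent:
    def test_starts_with_one_feature_strategy(self, config):
        for seed in range(20):
            state = init_agent(config, seed)
            assert state.current.complexity == 1
            assert state.control.level == LEVEL_ONE
            assert state.clock == 0.0

    def test_reproducible(self, config):
        a, b = init_agent(config, 7), init_agent(config, 7)
        assert a.current.matches_key() == b.current.matches_key()

    def test_initial_strategy_uniform_over_the_sixteen(self, config):
        counts = {}
        for seed in range(4000):
            key = init_agent(config, seed).current.matches_key()
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 16
        _, p = sps.chisquare(list(counts.values()))
        assert p > 1e-3


def test_config_labels_round_trip():
    for cfg in default_grid():
        assert config_from_label(cfg.label).label == cfg.label
    assert len({c.label for c in default_grid()}) == 18
    with pytest.raises(ValueError):
        config_from_label("banana")
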