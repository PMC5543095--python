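"""The strategy-switching cognitive agent.

The agent classifies tones with *strategies*: exemplar-like records pairing
one or two feature-value conditions with a response.  A strategy responds
with its stored response when the tone matches all of its conditions and
with the opposite response otherwise, so every strategy is a complete
classifier over the 16-tone space.  All 64 possible strategies (16
one-feature, 48 two-feature) are available in declarative memory from the
start; learning is the search through this space.

Search is driven purely by feedback:

* positive feedback keeps the current strategy and increments its success
  count until a threshold (``first_count`` for one-feature, ``second_count``
  for two-feature strategies) marks it "often successful";
* negative feedback triggers one of six update branches that range from
  flipping the response of a fresh strategy to declaring an environment
  change after an often-successful two-feature strategy fails repeatedly.

Retrieval from declarative memory is recency-constrained: a strategy
retrieved within the last ``finst_span_s`` simulated seconds (about 10-12
trials) is excluded, and the choice among the remaining eligible candidates
is uniform at random.  This hard recency window plus uniform choice stands
in for the architecture-level activation calculus of ACT-R; only the
behaviourally described ingredients (recency and randomness) are kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .task import FEATURES, FEATURE_VALUES, Feedback, Tone, feedback_for

LEVEL_ONE = "one_feature"
LEVEL_TWO = "two_feature"

#: Parameter grid explored by the sweep: success-count thresholds for
#: one-feature (3/4/5) and two-feature (6/8/10) strategies crossed with the
#: two recency-window spans (80/100 s) = 18 configurations.
FIRST_COUNTS = (3, 4, 5)
SECOND_COUNTS = (6, 8, 10)
FINST_SPANS = (80.0, 100.0)


@dataclass(frozen=True)
class ModelConfig:
    """Success-count thresholds and declarative recency window of one model.

    ``num_finsts`` optionally bounds how many recently used strategies are
    tracked at once (cognitive architectures typically keep a small fixed
    pool of such recency tags, e.g. four); the default ``None`` tracks every
    strategy used within the last ``finst_span_s`` seconds.
    """

    first_count: int = 3
    second_count: int = 6
    finst_span_s: float = 100.0
    num_finsts: int | None = None

    @property
    def label(self) -> str:
        return f"{self.first_count}_{self.second_count:02d}_{int(self.finst_span_s):03d}"

    def threshold_for(self, complexity: int) -> int:
        return self.first_count if complexity == 1 else self.second_count


def default_grid() -> list[ModelConfig]:
    """The 18 swept configurations, finst-major then second/first count."""
    return [
        ModelConfig(first, second, span)
        for span in FINST_SPANS
        for second in SECOND_COUNTS
        for first in FIRST_COUNTS
    ]


def config_from_label(label: str) -> ModelConfig:
    """Parse a ``"3_06_100"``-style label back into a :class:`ModelConfig`."""
    try:
        first, second, span = label.split("_")
        return ModelConfig(int(first), int(second), float(span))
    except ValueError as exc:
        raise ValueError(f"malformed config label {label!r}") from exc


@dataclass(eq=False)
class Strategy:
    """An exemplar pairing feature-value condition(s) with a response.

    ``conditions`` holds one or two ``(feature, value)`` pairs on distinct
    features, sorted by feature name.  Bookkeeping slots track how the
    strategy has fared: the capped success count, the sticky
    ``often_successful`` flag, the ``failed`` (negatively evaluated) flag,
    and the simulated time of the last retrieval (the recency "finst").
    """

    conditions: tuple[tuple[str, str], ...]
    response: int
    success_count: int = 0
    often_successful: bool = False
    failed: bool = False
    last_retrieved_at: float | None = None

    @property
    def complexity(self) -> int:
        return len(self.conditions)

    def matches_key(self) -> tuple:
        return (self.conditions, self.response)

    def describe(self) -> str:
        cond = " & ".join(f"{f}={v}" for f, v in self.conditions)
        return f"[{cond} -> {self.response}]"


@dataclass
class ControlState:
    """Metacognitive flags held alongside the current strategy.

    ``error_noted`` may only be true while the current strategy is often
    successful: it records that the trusted strategy has just failed once
    and is being re-evaluated rather than discarded.
    """

    level: str = LEVEL_ONE
    error_noted: bool = False
    env_change: bool = False


@dataclass
class DeclarativeStore:
    """Long-term memory holding all 64 strategies plus the recency tags.

    ``finst_log`` lists strategies in order of retrieval (most recent last);
    it backs the bounded pool of recency tags used by
    :func:`retrieve` to exclude recently used strategies.
    """

    strategies: list[Strategy]
    finst_log: list[Strategy] = field(default_factory=list)

    def note_retrieval(self, strategy: Strategy, now: float) -> None:
        strategy.last_retrieved_at = now
        try:
            self.finst_log.remove(strategy)
        except ValueError:
            pass
        self.finst_log.append(strategy)

    def clear_finst(self, strategy: Strategy) -> None:
        strategy.last_retrieved_at = None
        try:
            self.finst_log.remove(strategy)
        except ValueError:
            pass

    def recently_retrieved_ids(self, now: float, config: ModelConfig) -> set[int]:
        """Identities of strategies currently excluded by a recency tag."""
        tracked = (
            self.finst_log
            if config.num_finsts is None
            else self.finst_log[-config.num_finsts :]
        )
        return {
            id(s)
            for s in tracked
            if s.last_retrieved_at is not None
            and now - s.last_retrieved_at <= config.finst_span_s
        }

    def one_feature(self) -> list[Strategy]:
        return [s for s in self.strategies if s.complexity == 1]

    def two_feature(self) -> list[Strategy]:
        return [s for s in self.strategies if s.complexity == 2]

    def find(self, conditions: tuple[tuple[str, str], ...], response: int) -> Strategy:
        for s in self.strategies:
            if s.conditions == conditions and s.response == response:
                return s
        raise KeyError((conditions, response))


def enumerate_strategies() -> DeclarativeStore:
    """Fresh store: 16 one-feature and 48 two-feature strategies, all unused."""
    strategies: list[Strategy] = []
    for feature in FEATURES:
        for value in FEATURE_VALUES[feature]:
            for response in (1, 0):
                strategies.append(Strategy(((feature, value),), response))
    for fa, fb in itertools.combinations(FEATURES, 2):
        for va in FEATURE_VALUES[fa]:
            for vb in FEATURE_VALUES[fb]:
                conds = tuple(sorted(((fa, va), (fb, vb))))
                for response in (1, 0):
                    strategies.append(Strategy(conds, response))
    return DeclarativeStore(strategies)


@dataclass
class AgentState:
    """Complete agent state: memory, working-memory slot, control, clock."""

    store: DeclarativeStore
    current: Strategy
    control: ControlState
    clock: float
    rng: np.random.Generator


def init_agent(config: ModelConfig, seed) -> AgentState:
    """Start an agent with a uniformly random one-feature strategy.

    ``seed`` may be anything accepted by :func:`numpy.random.default_rng`,
    including an existing generator (which is then consumed in place).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    store = enumerate_strategies()
    one = store.one_feature()
    current = one[int(rng.integers(len(one)))]
    store.note_retrieval(current, 0.0)
    return AgentState(
        store=store,
        current=current,
        control=ControlState(),
        clock=0.0,
        rng=rng,
    )


def matches(strategy: Strategy, tone: Tone) -> bool:
    """True iff every condition feature-value equals the tone's value."""
    return all(tone.value(feature) == value for feature, value in strategy.conditions)


def choose_response(strategy: Strategy, tone: Tone) -> int:
    """React-same on a match, react-different otherwise."""
    if matches(strategy, tone):
        return strategy.response
    return 1 - strategy.response


def retrieve(
    store: DeclarativeStore,
    *,
    now: float,
    config: ModelConfig,
    rng: np.random.Generator,
    complexity: int,
    response: int | None = None,
    exclude: tuple[Strategy, ...] = (),
    forbid_conditions: tuple[tuple[str, str], ...] | None = None,
    share_one_condition_with: Strategy | None = None,
    ignore_failed: bool = False,
    ignore_finst: bool = False,
) -> Strategy | None:
    """Uniform random retrieval among eligible strategies.

    Eligible strategies satisfy the structural constraints, are not marked
    failed, and were not retrieved within the last ``finst_span_s`` seconds.
    Returns ``None`` when the eligible set is empty (a signalled outcome,
    not an error).  The chosen strategy's recency timestamp is set to
    ``now``.
    """
    recent = store.recently_retrieved_ids(now, config)
    candidates: list[Strategy] = []
    for s in store.strategies:
        if s.complexity != complexity:
            continue
        if any(s is e for e in exclude):
            continue
        if response is not None and s.response != response:
            continue
        if forbid_conditions is not None and s.conditions == forbid_conditions:
            continue
        if share_one_condition_with is not None:
            shared = len(set(s.conditions) & set(share_one_condition_with.conditions))
            if shared != 1:
                continue
        if not ignore_failed and s.failed:
            continue
        if not ignore_finst and id(s) in recent:
            continue
        candidates.append(s)
    if not candidates:
        return None
    chosen = candidates[int(rng.integers(len(candidates)))]
    store.note_retrieval(chosen, now)
    return chosen


def _retrieve_two_feature(
    state: AgentState, config: ModelConfig, share_with: Strategy | None = None
) -> Strategy:
    """Retrieve a two-feature strategy, never deadlocking.

    Two-feature retrieval is random among "any other" strategy not used
    recently: unlike the one-feature search, it does not filter on the
    negative-evaluation flag.  If the eligible set is empty the search is
    renewed by clearing the two-feature recency tags and retrying.  With
    ``share_with`` the candidate must keep exactly one of its condition
    pairs and its response (the within-level refinement move).
    """
    kwargs: dict = dict(
        now=state.clock,
        config=config,
        rng=state.rng,
        complexity=2,
        exclude=(state.current,),
        ignore_failed=True,
    )
    if share_with is not None:
        kwargs.update(response=share_with.response, share_one_condition_with=share_with)
    chosen = retrieve(state.store, **kwargs)
    if chosen is None:
        for s in state.store.two_feature():
            state.store.clear_finst(s)
        chosen = retrieve(state.store, **kwargs)
    if chosen is None:  # pragma: no cover - structurally impossible
        raise RuntimeError("two-feature retrieval failed after renewing the search")
    return chosen


def process_positive(state: AgentState, config: ModelConfig) -> AgentState:
    """Keep the current strategy and update its success bookkeeping.

    The count is capped at the applicable threshold; reaching it marks the
    strategy "often successful".  A success also ends any ongoing
    re-evaluation (clears ``error_noted``).
    """
    current = state.current
    threshold = config.threshold_for(current.complexity)
    if current.success_count < threshold:
        current.success_count += 1
        if current.success_count >= threshold:
            current.often_successful = True
    state.control.error_noted = False
    return state


def process_negative(state: AgentState, config: ModelConfig) -> AgentState:
    """Update the current strategy after negative feedback.

    Exactly one branch applies:

    a. an often-successful strategy failing for the first time is kept but
       flagged for re-evaluation;
    b. an often-successful strategy failing again while flagged is given up:
       a one-feature strategy triggers the switch to the two-feature level,
       a two-feature strategy signals an environment change (the strategy is
       marked failed) and a new two-feature strategy is retrieved;
    c. a one-feature strategy that fails before any success keeps its
       condition but flips its response;
    d. a one-feature strategy with some (sub-threshold) successes is marked
       failed and replaced by one with a different condition pair but the
       same response; if none can be retrieved the level switches to
       two-feature;
    e. a two-feature strategy failing before any success is marked failed
       and replaced by any other two-feature strategy;
    f. a two-feature strategy with sub-threshold successes is marked failed
       and replaced by one keeping one of its condition pairs and its
       response.
    """
    current = state.current
    control = state.control

    if current.often_successful:
        if not control.error_noted:  # (a) re-evaluate before giving up
            control.error_noted = True
            return state
        # (b) failed repeatedly
        control.error_noted = False
        state.store.note_retrieval(current, state.clock)  # just used: tag it
        if current.complexity == 1:
            control.level = LEVEL_TWO
            state.current = _retrieve_two_feature(state, config)
        else:
            control.env_change = True
            current.failed = True
            state.current = _retrieve_two_feature(state, config)
        return state

    if current.complexity == 1:
        if current.success_count == 0:
            # (c) immediate failure: same condition, flipped response.  The
            # retrieval is fully constrained, so the sibling is exempt from
            # the recency exclusion; its timestamp is still set.
            state.store.note_retrieval(current, state.clock)
            sibling = state.store.find(current.conditions, 1 - current.response)
            state.store.note_retrieval(sibling, state.clock)
            state.current = sibling
        else:
            # (d) change the feature-value pair, retain the response
            current.failed = True
            state.store.note_retrieval(current, state.clock)
            replacement = retrieve(
                state.store,
                now=state.clock,
                config=config,
                rng=state.rng,
                complexity=1,
                response=current.response,
                forbid_conditions=current.conditions,
                exclude=(current,),
            )
            if replacement is None:
                control.level = LEVEL_TWO
                replacement = _retrieve_two_feature(state, config)
            state.current = replacement
        return state

    # complexity 2, not often successful
    current.failed = True
    state.store.note_retrieval(current, state.clock)
    if current.success_count == 0:
        state.current = _retrieve_two_feature(state, config)  # (e)
    else:
        state.current = _retrieve_two_feature(state, config, share_with=current)  # (f)
    return state


def agent_trial(
    state: AgentState,
    tone: Tone,
    required: int,
    config: ModelConfig,
    trial_duration_s: float = 0.0,
    learn: bool = True,
) -> tuple[int, Feedback, AgentState]:
    """Run one trial: respond, receive feedback, update, advance the clock."""
    response = choose_response(state.current, tone)
    feedback = feedback_for(response, required)
    if learn:
        if feedback.positive:
            process_positive(state, config)
        else:
            process_negative(state, config)
    state.clock += trial_duration_s
    return response, feedback, state
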