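"""Session runner, run batches, and the 18-configuration parameter sweep.

A *run* is one agent completing one 240-trial session; its outcome is the
vector of 240 correct/incorrect flags, aggregated into 12 blocks of 20
trials.  A *batch* is 160 runs of one configuration, 40 per pseudo-random
order, over the four canonical sessions.  A *sweep* is one batch per
configuration of the default 18-cell parameter grid.

Seeding: every run's generator is derived as
``SeedSequence([master_seed, config_index, run_index])`` so any single run
can be reproduced in isolation, results are independent of execution order,
and distinct configurations never share streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agent import AgentState, ModelConfig, agent_trial, default_grid, init_agent
from .task import BLOCK_SIZE, N_BLOCKS, N_TRIALS, Session, canonical_sessions

N_RUNS_DEFAULT = 160


def block_proportions(correct: np.ndarray) -> np.ndarray:
    """Per-block proportion correct: 240 flags -> 12 means."""
    correct = np.asarray(correct, dtype=float)
    if correct.shape != (N_TRIALS,):
        raise ValueError(f"expected {N_TRIALS} correct flags, got {correct.shape}")
    return correct.reshape(N_BLOCKS, BLOCK_SIZE).mean(axis=1)


@dataclass
class RunResult:
    """One agent x one session: per-trial correctness and block means."""

    config: ModelConfig
    order_id: int
    run_seed: tuple
    correct: np.ndarray
    block_props: np.ndarray


@dataclass
class BatchResult:
    """All runs of one configuration plus across-run block statistics."""

    config: ModelConfig
    runs: list[RunResult]
    block_means: np.ndarray
    block_sds: np.ndarray

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def block_matrix(self) -> np.ndarray:
        """(n_runs, 12) matrix of per-run block proportions."""
        return np.vstack([r.block_props for r in self.runs])


def run_session(
    config: ModelConfig,
    session: Session,
    seed,
    learn: bool = True,
    log: list | None = None,
    state: AgentState | None = None,
) -> RunResult:
    """Run one agent through one session.

    ``seed`` seeds both the initial-strategy draw and every retrieval tie
    break.  Pass ``learn=False`` (with an explicit ``state``) to hold the
    current strategy fixed, e.g. for accuracy diagnostics.  If ``log`` is a
    list, one dict per trial is appended (strategy used, response, feedback,
    bookkeeping after the update).
    """
    if state is None:
        state = init_agent(config, np.random.default_rng(seed))
    correct = np.zeros(session.n_trials, dtype=bool)
    for i in range(1, session.n_trials + 1):
        tone = session.trials[i - 1]
        strategy = state.current
        response, feedback, state = agent_trial(
            state,
            tone,
            session.required(i),
            config,
            trial_duration_s=session.trial_durations[i - 1],
            learn=learn,
        )
        correct[i - 1] = feedback.positive
        if log is not None:
            log.append(
                {
                    "trial_index": i,
                    "strategy_conditions": "&".join(
                        f"{f}={v}" for f, v in strategy.conditions
                    ),
                    "strategy_response": strategy.response,
                    "complexity": strategy.complexity,
                    "matched": int(response == strategy.response),
                    "response": response,
                    "feedback": "positive" if feedback.positive else "negative",
                    "success_count": strategy.success_count,
                    "error_noted": int(state.control.error_noted),
                    "env_change": int(state.control.env_change),
                    "level": state.control.level,
                }
            )
    try:
        seed_key = (int(seed),)
    except (TypeError, ValueError):
        seed_key = (str(seed),)
    return RunResult(
        config=config,
        order_id=session.order_id,
        run_seed=seed_key,
        correct=correct,
        block_props=block_proportions(correct),
    )


def _run_seed(master_seed: int, config_index: int, run_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([master_seed, config_index, run_index])


def run_batch(
    config: ModelConfig,
    n_runs: int = N_RUNS_DEFAULT,
    master_seed: int = 0,
    config_index: int = 0,
    sessions: dict[int, Session] | None = None,
) -> BatchResult:
    """Run ``n_runs`` seeded runs of one configuration, n_runs/4 per order.

    The four canonical sessions are reused across configurations; run ``i``
    uses order ``1 + (i mod 4)`` and the seed sequence
    ``[master_seed, config_index, i]``.
    """
    if n_runs % 4 != 0:
        raise ValueError("n_runs must be divisible by 4 (40 runs per order at full scale)")
    if sessions is None:
        sessions = canonical_sessions()
    runs = []
    for i in range(n_runs):
        order_id = 1 + (i % 4)
        rng = np.random.default_rng(_run_seed(master_seed, config_index, i))
        result = run_session(config, sessions[order_id], rng)
        result.run_seed = (master_seed, config_index, i)
        runs.append(result)
    matrix = np.vstack([r.block_props for r in runs])
    return BatchResult(
        config=config,
        runs=runs,
        block_means=matrix.mean(axis=0),
        block_sds=matrix.std(axis=0, ddof=1),
    )


def run_sweep(
    grid: list[ModelConfig] | None = None,
    n_runs: int = N_RUNS_DEFAULT,
    master_seed: int = 0,
) -> list[BatchResult]:
    """One batch per configuration (default: the full 18-cell grid)."""
    if grid is None:
        grid = default_grid()
    sessions = canonical_sessions()
    return [
        run_batch(config, n_runs=n_runs, master_seed=master_seed,
                  config_index=ci, sessions=sessions)
        for ci, config in enumerate(grid)
    ]
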