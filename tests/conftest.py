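"""Shared fixtures: hand-built toy sessions and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from revlearn.task_env import (
    N_OPTIONS,
    RewardSchedule,
    Session,
    TrialRecord,
)


def make_session(
    choices,
    rewards,
    latencies=None,
    *,
    subject_id: str = "T1",
    group: str = "control",
    phase: str = "pre",
    kind: str = "fixed1",
    reversal: int | None = None,
    session_id: str = "s1",
) -> Session:
    """Build a session directly from choice/reward vectors (uniform schedule)."""
    choices = np.asarray(choices, dtype=int)
    rewards = np.asarray(rewards, dtype=int)
    assert choices.shape == rewards.shape
    if latencies is None:
        latencies = np.full(len(choices), 400.0)
    probs = np.full((len(choices), N_OPTIONS), 1.0 / 3.0)
    schedule = RewardSchedule(kind=kind, probs=probs, reversal_trial=reversal)
    trials = [
        TrialRecord(trial=t + 1, config_id=1, choice=int(c), reward=int(r), latency_ms=float(l))
        for t, (c, r, l) in enumerate(zip(choices, rewards, latencies))
    ]
    return Session(
        subject_id=subject_id,
        group=group,
        phase=phase,
        schedule=schedule,
        trials=trials,
        session_id=session_id,
    )


def random_toy_sessions(rng: np.random.Generator, n_sessions: int, length=(10, 40)) -> list[Session]:
    """Random choice/reward sessions for oracle-equivalence tests."""
    out = []
    for i in range(n_sessions):
        T = int(rng.integers(length[0], length[1] + 1))
        choices = rng.integers(0, N_OPTIONS, size=T)
        rewards = rng.integers(0, 2, size=T)
        out.append(make_session(choices, rewards, session_id=f"toy{i}"))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_sessions(rng) -> list[Session]:
    return random_toy_sessions(rng, 20)
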