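"""Three-option bandit task environments.

Reward schedules assign each of three stimulus options an independent
Bernoulli reward probability on every trial.  Two families are provided:

* *Varying* schedules (``stable``, ``variable``): 300 trials in which the
  per-option probabilities drift as bounded smoothed random walks and the
  identity of the best option reverses after trial 150.  The ``stable`` and
  ``variable`` members generated from the same seed differ only in the
  pre-reversal probability trace of the initially-best option; the
  ``variable`` trace fluctuates much more strongly during initial learning.
* *Fixed* schedules (levels 1-3): 150 trials of constant probabilities with
  a common option ratio; level 2 scales the level-1 yield by 0.75 and
  level 3 by 0.5.

The module also runs the trial loop (:func:`play_session`) for an arbitrary
agent policy and derives schedule-based labels: the 20-trial moving-window
reward likelihood and the objectively best option per trial (``V1_sch``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

N_OPTIONS = 3
N_CONFIGS = 4

VARYING_KINDS = ("stable", "variable")
FIXED_KINDS = ("fixed1", "fixed2", "fixed3")
SCHEDULE_KINDS = VARYING_KINDS + FIXED_KINDS

#: trials per session for the drifting-probability schedules
VARYING_N_TRIALS = 300
#: trial after which the best-option identity swaps (trials 1..150 are pre)
REVERSAL_TRIAL = 150
#: trials per session for the constant-probability schedules
FIXED_N_TRIALS = 150

#: default constant probabilities for the level-1 fixed schedule
DEFAULT_FIXED_BASE = (0.8, 0.5, 0.2)
FIXED_LEVEL_SCALE = {1: 1.0, 2: 0.75, 3: 0.5}

# Probability bands for the varying-schedule random walks.  Bands of the
# best and runner-up option never overlap, which guarantees a single
# moving-average crossing at the reversal.
_BAND_HIGH = (0.55, 0.90)
_BAND_MID = (0.15, 0.50)
_BAND_LOW = (0.05, 0.35)


@dataclass(frozen=True)
class RewardSchedule:
    """Per-trial Bernoulli reward probabilities for the three options."""

    kind: str
    probs: np.ndarray  # T x 3, float in [0, 1]
    reversal_trial: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != N_OPTIONS:
            raise ValueError(f"probs must be T x {N_OPTIONS}, got {probs.shape}")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("reward probabilities must lie in [0, 1]")
        if self.kind not in SCHEDULE_KINDS:
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        object.__setattr__(self, "probs", probs)

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    @property
    def is_varying(self) -> bool:
        return self.kind in VARYING_KINDS


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial: what was on screen, what was chosen, what happened."""

    trial: int  # 1-based
    config_id: int  # spatial configuration, 1..4
    choice: int  # option index 0..2
    reward: int  # 0/1
    latency_ms: float

    def __post_init__(self) -> None:
        if self.choice not in range(N_OPTIONS):
            raise ValueError(f"choice must be in 0..{N_OPTIONS - 1}, got {self.choice}")
        if self.reward not in (0, 1):
            raise ValueError(f"reward must be 0/1, got {self.reward}")
        if not self.latency_ms > 0:
            raise ValueError(f"latency_ms must be positive, got {self.latency_ms}")
        if self.config_id not in range(1, N_CONFIGS + 1):
            raise ValueError(f"config_id must be in 1..{N_CONFIGS}, got {self.config_id}")


@dataclass
class Session:
    """An ordered run of trials by one subject under one schedule."""

    subject_id: str
    group: str  # "control" | "mdmc"
    phase: str  # "pre" | "post"
    schedule: RewardSchedule
    trials: list[TrialRecord] = field(default_factory=list)
    session_id: str = "s1"

    def __post_init__(self) -> None:
        if self.group not in ("control", "mdmc"):
            raise ValueError(f"group must be 'control' or 'mdmc', got {self.group!r}")
        if self.phase not in ("pre", "post"):
            raise ValueError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        for i, tr in enumerate(self.trials, start=1):
            if tr.trial != i:
                raise ValueError("trial indices must be contiguous from 1")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def choices(self) -> np.ndarray:
        return np.array([t.choice for t in self.trials], dtype=int)

    @property
    def rewards(self) -> np.ndarray:
        return np.array([t.reward for t in self.trials], dtype=int)

    @property
    def latencies_ms(self) -> np.ndarray:
        return np.array([t.latency_ms for t in self.trials], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "phase": self.phase,
                "schedule_kind": self.schedule.kind,
                "session_id": self.session_id,
                "trial": [t.trial for t in self.trials],
                "config_id": [t.config_id for t in self.trials],
                "choice": [t.choice for t in self.trials],
                "reward": [t.reward for t in self.trials],
                "latency_ms": [t.latency_ms for t in self.trials],
            }
        )


class Policy(Protocol):
    """Agent interface consumed by :func:`play_session`.

    A policy is stateful within a session: :meth:`start_session` resets it,
    :meth:`action_probs` returns the current choice distribution over the
    three options, and :meth:`update` feeds back the chosen option and its
    outcome.
    """

    def start_session(self) -> None: ...

    def action_probs(self) -> np.ndarray: ...

    def update(self, choice: int, reward: int) -> None: ...


def _bounded_walk(
    rng: np.random.Generator,
    n: int,
    lo: float,
    hi: float,
    sigma: float,
    start: float | None = None,
) -> np.ndarray:
    """Gaussian random walk reflected into [lo, hi], lightly smoothed."""
    if start is None:
        start = 0.5 * (lo + hi)
    steps = rng.normal(0.0, sigma, size=n)
    raw = start + np.cumsum(steps)
    # reflect into the band
    span = hi - lo
    folded = np.mod(raw - lo, 2 * span)
    folded = np.where(folded > span, 2 * span - folded, folded) + lo
    # mild smoothing keeps trial-to-trial fluctuation "continuous"
    return pd.Series(folded).rolling(5, center=True, min_periods=1).mean().to_numpy()


def generate_varying_schedule(
    kind: str,
    seed: int,
    *,
    n_trials: int = VARYING_N_TRIALS,
    reversal_trial: int = REVERSAL_TRIAL,
    stable_sigma: float = 0.0015,
    variable_sigma: float = 0.035,
    other_sigma: float = 0.02,
) -> RewardSchedule:
    """Generate a 300-trial drifting schedule with a mid-session reversal.

    Option 0 is the best option for trials ``1..reversal_trial`` and option 1
    thereafter.  For a fixed ``seed``, the ``stable`` and ``variable`` kinds
    share every probability trace except option 0's pre-reversal segment,
    which is near-constant under ``stable`` and a volatile walk under
    ``variable``.
    """
    if kind not in VARYING_KINDS:
        raise ValueError(f"kind must be one of {VARYING_KINDS}, got {kind!r}")
    if not 0 < reversal_trial < n_trials:
        raise ValueError("reversal_trial must fall strictly inside the session")
    for name, s in (("stable_sigma", stable_sigma), ("variable_sigma", variable_sigma), ("other_sigma", other_sigma)):
        if not 0 <= s <= 0.2:
            raise ValueError(f"{name} must be in [0, 0.2], got {s}")

    n_pre = reversal_trial
    n_post = n_trials - reversal_trial

    # Component RNGs keyed by fixed spawn ids so that shared traces are
    # byte-identical between the stable and variable kinds.
    def child(key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))

    opt1_pre = _bounded_walk(child(1), n_pre, *_BAND_MID, other_sigma)
    opt1_post = _bounded_walk(child(2), n_post, *_BAND_HIGH, other_sigma)
    opt2 = _bounded_walk(child(3), n_trials, *_BAND_LOW, other_sigma)
    opt0_post = _bounded_walk(child(4), n_post, *_BAND_MID, other_sigma, start=_BAND_MID[0] + 0.1)
    if kind == "stable":
        opt0_pre = _bounded_walk(child(5), n_pre, *_BAND_HIGH, stable_sigma, start=0.75)
    else:
        opt0_pre = _bounded_walk(child(6), n_pre, *_BAND_HIGH, variable_sigma, start=0.75)

    probs = np.column_stack(
        [
            np.concatenate([opt0_pre, opt0_post]),
            np.concatenate([opt1_pre, opt1_post]),
            opt2,
        ]
    )
    return RewardSchedule(kind=kind, probs=probs, reversal_trial=reversal_trial, seed=seed)


def generate_fixed_schedule(
    level: int,
    base_probs: Sequence[float] = DEFAULT_FIXED_BASE,
    *,
    n_trials: int = FIXED_N_TRIALS,
) -> RewardSchedule:
    """Constant-probability schedule; levels 2 and 3 scale the yield by 0.75 / 0.5."""
    if level not in FIXED_LEVEL_SCALE:
        raise ValueError(f"level must be 1, 2 or 3, got {level}")
    base = np.asarray(base_probs, dtype=float)
    if base.shape != (N_OPTIONS,):
        raise ValueError("base_probs must be a 3-vector")
    if not (np.all(np.diff(base) < 0) and np.all(base > 0) and np.all(base <= 1)):
        raise ValueError("base_probs must be strictly decreasing and in (0, 1]")
    scaled = base * FIXED_LEVEL_SCALE[level]
    if np.any(scaled > 1):
        raise ValueError("scaled probabilities exceed 1")
    probs = np.tile(scaled, (n_trials, 1))
    return RewardSchedule(kind=f"fixed{level}", probs=probs, reversal_trial=None, seed=None)


def moving_window_prob(
    values: Sequence[float] | np.ndarray,
    window: int = 20,
    *,
    alignment: str = "centered",
) -> np.ndarray:
    """Moving-window mean of a per-trial series.

    ``centered`` averages over +/- window/2 trials around each trial
    (window/2 on each side plus the trial itself), truncating at the session
    edges; ``trailing`` averages the last ``window`` trials ending at each
    trial.  Output has the same length as the input.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty series")
    if window < 2 or window % 2 != 0:
        raise ValueError(f"window must be even and >= 2, got {window}")
    s = pd.Series(vals)
    if alignment == "centered":
        out = s.rolling(window + 1, center=True, min_periods=1).mean()
    elif alignment == "trailing":
        out = s.rolling(window, min_periods=1).mean()
    else:
        raise ValueError(f"alignment must be 'centered' or 'trailing', got {alignment!r}")
    return out.to_numpy()


def v1_sch_labels(
    schedule: RewardSchedule,
    window: int = 20,
    *,
    alignment: str = "centered",
) -> np.ndarray:
    """Objectively best option per trial: argmax of the smoothed probabilities.

    Ties break to the lowest option index.
    """
    smoothed = np.column_stack(
        [moving_window_prob(schedule.probs[:, c], window, alignment=alignment) for c in range(N_OPTIONS)]
    )
    return np.argmax(smoothed, axis=1)


@dataclass
class LatencyModel:
    """Lognormal response-latency generator with an additive switch cost.

    ``log latency ~ Normal(log(base_ms) + switch_add * is_switch, sigma)``.
    The switch cost is expressed in log-ms units so a positive value slows
    switch trials multiplicatively.
    """

    base_ms: float = 400.0
    switch_add_log: float = 0.25
    sigma: float = 0.25

    def draw(self, rng: np.random.Generator, is_switch: bool) -> float:
        mu = np.log(self.base_ms) + (self.switch_add_log if is_switch else 0.0)
        return float(np.exp(rng.normal(mu, self.sigma)))


def play_session(
    schedule: RewardSchedule,
    policy: Policy,
    seed: int,
    *,
    subject_id: str = "sim",
    group: str = "control",
    phase: str = "pre",
    session_id: str = "s1",
    latency_model: LatencyModel | None = None,
) -> Session:
    """Run one session of the task.

    Per trial: draw the choice from the policy's current distribution, then
    draw the reward as an independent Bernoulli from that option's scheduled
    probability (outcomes on unchosen options are never held over).  Spatial
    configuration ids are drawn uniformly from 1..4.  Fully deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    if latency_model is None:
        latency_model = getattr(policy, "latency", None) or LatencyModel()
    policy.start_session()
    trials: list[TrialRecord] = []
    prev_choice: int | None = None
    for t in range(schedule.n_trials):
        p = np.asarray(policy.action_probs(), dtype=float)
        if p.shape != (N_OPTIONS,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"policy returned an invalid choice distribution: {p}")
        choice = int(rng.choice(N_OPTIONS, p=p))
        reward = int(rng.random() < schedule.probs[t, choice])
        config_id = int(rng.integers(1, N_CONFIGS + 1))
        is_switch = prev_choice is not None and choice != prev_choice
        latency = latency_model.draw(rng, is_switch)
        policy.update(choice, reward)
        trials.append(
            TrialRecord(trial=t + 1, config_id=config_id, choice=choice, reward=reward, latency_ms=latency)
        )
        prev_choice = choice
    return Session(
        subject_id=subject_id,
        group=group,
        phase=phase,
        schedule=schedule,
        trials=trials,
        session_id=session_id,
    )
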