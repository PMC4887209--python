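"""Synthetic agents that generate behavior for the analysis pipeline.

Three policy families:

* :class:`RWPolicy` — a control value learner: Rescorla-Wagner updates with
  Boltzmann choice.
* :class:`LesionPolicy` — the same learner with a degraded short-term record
  of its own recent choices, an eligibility-trace-style mechanism: the value
  update from an outcome is attenuated whenever the chosen option was picked
  only rarely over the last few trials.  Credit for outcomes of
  frequently-chosen (well-established) options is assigned normally, so the
  long-run choice trend is preserved while credit for recent switches is
  lost.
* :class:`KernelPolicy` — a ground-truth generator for the lagged
  choice x outcome regression: it scores each option with a planted weight
  grid applied to exactly the regression's 36 EVs and chooses by a
  multinomial logistic rule.

:func:`simulate_cohort` turns a declarative config (subjects, groups,
phases, schedules, per-cell agent parameters, seeds) into a fully
reproducible set of sessions emulating the study design: 7 controls and 3
lesioned subjects, 5 sessions per schedule per phase, with the lesion
mechanism active only in the lesion group's post phase.
"""

from __future__ import annotations

import zlib
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import kernel as _kernel
from .rl import DEFAULT_INIT_VALUE, softmax_probs
from .task_env import (
    N_OPTIONS,
    LatencyModel,
    RewardSchedule,
    Session,
    generate_fixed_schedule,
    generate_varying_schedule,
    play_session,
)


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the simulated value learners.

    ``trace_span`` is how many recent trials count as "recent" when deciding
    whether a chosen option is well-established; ``trace_atten`` scales the
    value update for options chosen fewer than ``trace_thresh`` times within
    that span (1.0 = intact control, < 1 = degraded recent-choice record).
    Latencies are lognormal with an additive switch cost on the log scale.
    """

    alpha: float = 0.3
    beta_sm: float = 5.0
    init_value: float = DEFAULT_INIT_VALUE
    trace_span: int = 5
    trace_atten: float = 1.0
    trace_thresh: int = 2
    latency_base_ms: float = 400.0
    latency_switch_add: float = 0.25  # log-ms units
    latency_sigma: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta_sm < 0:
            raise ValueError(f"beta_sm must be >= 0, got {self.beta_sm}")
        if not 0.0 <= self.trace_atten <= 1.0:
            raise ValueError(f"trace_atten must be in [0, 1], got {self.trace_atten}")
        if self.trace_span < 1:
            raise ValueError("trace_span must be >= 1")

    @property
    def latency(self) -> LatencyModel:
        return LatencyModel(
            base_ms=self.latency_base_ms,
            switch_add_log=self.latency_switch_add,
            sigma=self.latency_sigma,
        )


#: control-group defaults (intact trace)
CONTROL_PARAMS = AgentParams()
#: lesion-group post-surgery defaults: attenuated credit for rarely-chosen
#: options, generally faster responding, no switch cost
LESION_PARAMS = AgentParams(
    trace_atten=0.2,
    latency_base_ms=300.0,
    latency_switch_add=0.0,
)


class RWPolicy:
    """Rescorla-Wagner learner with softmax choice."""

    def __init__(self, params: AgentParams):
        self.params = params
        self.latency = params.latency
        self.values = np.full(N_OPTIONS, params.init_value, dtype=float)

    def start_session(self) -> None:
        self.values = np.full(N_OPTIONS, self.params.init_value, dtype=float)

    def action_probs(self) -> np.ndarray:
        return softmax_probs(self.values, self.params.beta_sm)

    def update(self, choice: int, reward: int) -> None:
        v = self.values[choice]
        self.values[choice] = v + self.params.alpha * (reward - v)


class LesionPolicy(RWPolicy):
    """RW learner whose updates for recently-switched-to options are attenuated.

    If the chosen option appears fewer than ``trace_thresh`` times among the
    previous ``trace_span`` choices, the update's learning rate is scaled by
    ``trace_atten``; otherwise the update is intact.  With
    ``trace_atten = 1`` the policy is behaviorally identical to
    :class:`RWPolicy`.
    """

    def __init__(self, params: AgentParams):
        super().__init__(params)
        self._recent: deque[int] = deque(maxlen=params.trace_span)

    def start_session(self) -> None:
        super().start_session()
        self._recent = deque(maxlen=self.params.trace_span)

    def update(self, choice: int, reward: int) -> None:
        p = self.params
        recent_count = sum(1 for c in self._recent if c == choice)
        scale = p.trace_atten if recent_count < p.trace_thresh else 1.0
        v = self.values[choice]
        self.values[choice] = v + scale * p.alpha * (reward - v)
        self._recent.append(choice)


def rw_agent(params: AgentParams) -> RWPolicy:
    return RWPolicy(params)


def lesion_agent(params: AgentParams) -> LesionPolicy:
    if params.trace_atten >= 1.0:
        # legal (identity case) but worth allowing silently: used in tests
        pass
    return LesionPolicy(params)


@dataclass(frozen=True)
class PlantedKernel:
    """Ground-truth weights for the lagged choice x outcome regression.

    ``grid[i-1, j-1]`` weights the EV pairing the choice i trials back with
    the outcome j trials back (i, j = 1..5); ``confound`` holds the 11
    lag-6 weights in the regression's column order.
    """

    grid: np.ndarray  # 5 x 5
    intercept: float = 0.0
    confound: np.ndarray = field(default_factory=lambda: np.zeros(_kernel.N_CONFOUND))

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        confound = np.asarray(self.confound, dtype=float)
        if grid.shape != (_kernel.INTEREST_LAG, _kernel.INTEREST_LAG):
            raise ValueError(f"grid must be 5x5, got {grid.shape}")
        if confound.shape != (_kernel.N_CONFOUND,):
            raise ValueError(f"confound must have {_kernel.N_CONFOUND} entries")
        if not (np.all(np.isfinite(grid)) and np.all(np.isfinite(confound))):
            raise ValueError("kernel weights must be finite")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "confound", confound)

    def as_beta(self) -> np.ndarray:
        """Full 36-vector in the regression's column order."""
        beta = np.empty(_kernel.N_EV)
        ci = 0
        for k, (i, j) in enumerate(_kernel.COLUMN_LAGS):
            if i <= _kernel.INTEREST_LAG and j <= _kernel.INTEREST_LAG:
                beta[k] = self.grid[i - 1, j - 1]
            else:
                beta[k] = self.confound[ci]
                ci += 1
        return beta


class KernelPolicy:
    """Chooses by a multinomial logistic rule over planted-kernel scores.

    At each trial every option's 36-EV feature vector is computed exactly as
    the regression defines it and scored against the planted weights; the
    choice is softmax over the three scores.  Until six trials of history
    exist the policy chooses uniformly (warm-up).
    """

    def __init__(self, planted: PlantedKernel):
        self.planted = planted
        self._beta = planted.as_beta()
        self.latency = LatencyModel()
        self._choices: list[int] = []
        self._rewards: list[int] = []

    def start_session(self) -> None:
        self._choices = []
        self._rewards = []

    def action_probs(self) -> np.ndarray:
        t = len(self._choices)
        if t < _kernel.MAX_LAG:
            return np.full(N_OPTIONS, 1.0 / N_OPTIONS)
        ch = np.asarray(self._choices)
        rw = np.asarray(self._rewards)
        scores = np.array(
            [
                self.planted.intercept + self._beta @ _kernel.lagged_features(ch, rw, t, target)
                for target in range(N_OPTIONS)
            ]
        )
        return softmax_probs(scores, 1.0)

    def update(self, choice: int, reward: int) -> None:
        self._choices.append(choice)
        self._rewards.append(reward)


def kernel_agent(planted: PlantedKernel) -> KernelPolicy:
    return KernelPolicy(planted)


def make_policy(params_or_kernel: AgentParams | PlantedKernel, lesion: bool = False):
    if isinstance(params_or_kernel, PlantedKernel):
        return KernelPolicy(params_or_kernel)
    if lesion or params_or_kernel.trace_atten < 1.0:
        return LesionPolicy(params_or_kernel)
    return RWPolicy(params_or_kernel)


@dataclass
class CohortConfig:
    """Declarative description of a simulated cohort.

    ``params`` maps (group, phase) to the agent parameters used for that
    cell; cells not listed fall back to the control defaults.  Every session
    seed is derived deterministically from ``master_seed`` and the session's
    identity, so rerunning the same config reproduces every session exactly.
    """

    control_subjects: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5", "C6", "C7")
    lesion_subjects: tuple[str, ...] = ("MD1", "MD2", "MD3")
    phases: tuple[str, ...] = ("pre", "post")
    schedule_kinds: tuple[str, ...] = ("stable", "variable")
    sessions_per_schedule: int = 5
    master_seed: int = 0
    params: dict[tuple[str, str], AgentParams] = field(default_factory=dict)
    fixed_base_probs: tuple[float, float, float] = (0.8, 0.5, 0.2)

    def params_for(self, group: str, phase: str) -> AgentParams:
        if (group, phase) in self.params:
            return self.params[(group, phase)]
        if group == "mdmc" and phase == "post":
            return LESION_PARAMS
        return CONTROL_PARAMS


def _session_seed(master_seed: int, *identity: str | int) -> np.random.SeedSequence:
    # stable across processes (unlike hash())
    key = tuple(zlib.crc32(str(x).encode()) & 0x7FFFFFFF for x in identity)
    return np.random.SeedSequence(master_seed, spawn_key=key)


def _make_schedule(kind: str, seed_seq: np.random.SeedSequence, base_probs) -> RewardSchedule:
    if kind in ("stable", "variable"):
        return generate_varying_schedule(kind, int(seed_seq.generate_state(1)[0] & 0x7FFFFFFF))
    level = int(kind[-1])
    return generate_fixed_schedule(level, base_probs)


def simulate_cohort(config: CohortConfig) -> list[Session]:
    """Simulate every subject x phase x schedule x session cell of the design.

    Fixed-schedule kinds are simulated post-phase only (as collected in the
    study); varying kinds run in both phases.  Duplicate subject ids are
    rejected.
    """
    all_subjects = list(config.control_subjects) + list(config.lesion_subjects)
    if len(set(all_subjects)) != len(all_subjects):
        raise ValueError("duplicate subject ids in cohort config")

    sessions: list[Session] = []
    for group, subjects in (
        ("control", config.control_subjects),
        ("mdmc", config.lesion_subjects),
    ):
        for subject in subjects:
            for phase in config.phases:
                params = config.params_for(group, phase)
                for kind in config.schedule_kinds:
                    if kind.startswith("fixed") and phase == "pre":
                        continue
                    for s_idx in range(1, config.sessions_per_schedule + 1):
                        seed_seq = _session_seed(config.master_seed, subject, phase, kind, s_idx)
                        sched_seq, play_seq = seed_seq.spawn(2)
                        schedule = _make_schedule(kind, sched_seq, config.fixed_base_probs)
                        policy = make_policy(params, lesion=(group == "mdmc" and phase == "post"))
                        session = play_session(
                            schedule,
                            policy,
                            int(play_seq.generate_state(1)[0] & 0x7FFFFFFF),
                            subject_id=subject,
                            group=group,
                            phase=phase,
                            session_id=f"{kind}_{s_idx}",
                            latency_model=params.latency,
                        )
                        sessions.append(session)
    return sessions


def random_planted_kernel(
    rng: np.random.Generator,
    scale: float = 0.6,
    diag_boost: float = 0.8,
) -> PlantedKernel:
    """A random but learnable ground-truth kernel for recovery studies.

    Off-diagonal weights ~ N(0, scale^2); the contingent diagonal gets a
    positive boost so the agent shows realistic win-stay structure.
    """
    grid = rng.normal(0.0, scale, size=(_kernel.INTEREST_LAG, _kernel.INTEREST_LAG))
    grid[np.diag_indices(_kernel.INTEREST_LAG)] += diag_boost
    confound = rng.normal(0.0, 0.2 * scale, size=_kernel.N_CONFOUND)
    return PlantedKernel(grid=grid, confound=confound)
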