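"""Readers and writers for session and schedule tables (tidy TSV).

Session files carry one row per trial with the columns

    subject_id  group  phase  schedule_kind  session_id  trial  config_id
    choice  reward  latency_ms

and may hold several sessions (grouped by the identity columns).  Schedule
files have columns ``trial  p_opt0  p_opt1  p_opt2`` plus ``#``-prefixed
metadata lines (kind, seed, reversal_trial) at the top.  All files are
tab-separated, UTF-8, with a header row; validation failures report the
file and offending rows and fail hard by default.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .agents import AgentParams, CohortConfig
from .task_env import (
    N_CONFIGS,
    N_OPTIONS,
    RewardSchedule,
    Session,
    TrialRecord,
)

SESSION_COLUMNS = [
    "subject_id",
    "group",
    "phase",
    "schedule_kind",
    "session_id",
    "trial",
    "config_id",
    "choice",
    "reward",
    "latency_ms",
]
SESSION_KEY = ["subject_id", "group", "phase", "schedule_kind", "session_id"]


def write_schedule(schedule: RewardSchedule, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# kind: {schedule.kind}\n")
        if schedule.seed is not None:
            fh.write(f"# seed: {schedule.seed}\n")
        if schedule.reversal_trial is not None:
            fh.write(f"# reversal_trial: {schedule.reversal_trial}\n")
        fh.write("trial\tp_opt0\tp_opt1\tp_opt2\n")
        for t in range(schedule.n_trials):
            p = schedule.probs[t]
            fh.write(f"{t + 1}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\n")


def read_schedule(path: str | Path) -> RewardSchedule:
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            k, _, v = line.lstrip("# ").partition(":")
            meta[k.strip()] = v.strip()
        else:
            body.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t")
    required = ["trial", "p_opt0", "p_opt1", "p_opt2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if not np.array_equal(df["trial"].to_numpy(), np.arange(1, len(df) + 1)):
        raise ValueError(f"{path}: trial indices must be contiguous from 1")
    probs = df[["p_opt0", "p_opt1", "p_opt2"]].to_numpy()
    return RewardSchedule(
        kind=meta.get("kind", "fixed1"),
        probs=probs,
        reversal_trial=int(meta["reversal_trial"]) if "reversal_trial" in meta else None,
        seed=int(meta["seed"]) if "seed" in meta else None,
    )


def sessions_to_frame(sessions: Iterable[Session]) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in sessions], ignore_index=True)


def write_sessions(sessions: Iterable[Session], path: str | Path) -> None:
    # full float precision so a write -> read round trip is exact
    sessions_to_frame(sessions).to_csv(path, sep="\t", index=False)


def _frame_to_sessions(df: pd.DataFrame, source: str, schedules: dict | None) -> list[Session]:
    sessions = []
    for key, grp in df.groupby(SESSION_KEY, sort=False):
        subject_id, group, phase, schedule_kind, session_id = key
        grp = grp.reset_index(drop=True)
        trials_idx = grp["trial"].to_numpy()
        if not np.array_equal(trials_idx, np.arange(1, len(grp) + 1)):
            raise ValueError(
                f"{source}: session {key}: trial indices must be contiguous from 1"
            )
        bad = grp.index[~grp["choice"].isin(range(N_OPTIONS))].tolist()
        if bad:
            raise ValueError(f"{source}: session {key}: invalid choice at rows {bad}")
        bad = grp.index[~grp["reward"].isin((0, 1))].tolist()
        if bad:
            raise ValueError(f"{source}: session {key}: invalid reward at rows {bad}")
        bad = grp.index[~grp["config_id"].isin(range(1, N_CONFIGS + 1))].tolist()
        if bad:
            raise ValueError(f"{source}: session {key}: invalid config_id at rows {bad}")
        schedule = None
        if schedules is not None:
            schedule = schedules.get(schedule_kind)
        if schedule is None:
            # placeholder schedule of the right length so session invariants hold
            n = len(grp)
            probs = np.full((n, N_OPTIONS), np.nan)
            probs[:] = 1.0 / 3.0
            reversal = 150 if schedule_kind in ("stable", "variable") else None
            schedule = RewardSchedule(kind=schedule_kind, probs=probs, reversal_trial=reversal)
        trials = [
            TrialRecord(
                trial=int(r.trial),
                config_id=int(r.config_id),
                choice=int(r.choice),
                reward=int(r.reward),
                latency_ms=float(r.latency_ms),
            )
            for r in grp.itertuples()
        ]
        sessions.append(
            Session(
                subject_id=str(subject_id),
                group=str(group),
                phase=str(phase),
                schedule=schedule,
                trials=trials,
                session_id=str(session_id),
            )
        )
    return sessions


def read_sessions(
    paths: Sequence[str | Path] | str | Path,
    schedules: dict[str, RewardSchedule] | None = None,
) -> list[Session]:
    """Read and validate session TSVs.

    ``schedules`` optionally maps schedule_kind to the generating
    :class:`RewardSchedule`; sessions whose kind is not supplied get a
    placeholder uniform schedule (sufficient for every analysis that does
    not need the programmed probabilities).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    sessions: list[Session] = []
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in SESSION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        sessions.extend(_frame_to_sessions(df, str(path), schedules))
    return sessions


def read_cohort_config(path: str | Path) -> CohortConfig:
    """Load a cohort config from YAML.

    Recognized keys mirror :class:`revlearn.agents.CohortConfig`; the
    ``params`` block maps "<group>.<phase>" to AgentParams fields.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    params = {}
    for key, fields in (raw.pop("params", None) or {}).items():
        group, _, phase = key.partition(".")
        params[(group, phase)] = AgentParams(**fields)
    known = {
        "control_subjects",
        "lesion_subjects",
        "phases",
        "schedule_kinds",
        "sessions_per_schedule",
        "master_seed",
        "fixed_base_probs",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown cohort config keys {sorted(unknown)}")
    for k in ("control_subjects", "lesion_subjects", "phases", "schedule_kinds", "fixed_base_probs"):
        if k in raw:
            raw[k] = tuple(raw[k])
    return CohortConfig(params=params, **raw)
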