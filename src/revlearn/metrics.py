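"""Descriptive behavioral analyses for three-option bandit sessions.

Covers: switch/stay probabilities conditioned on the previous outcome and
reversal phase; the A_kB run-history tables (how a run of k choices of one
option before a single switch to another modulates the next choice);
choice-frequency tables (repeat probability as a function of how often the
just-chosen option appeared over the last five trials); trials-to-criterion
and best-option choice summaries; log-latency stay/switch comparisons; and
the fixed-schedule EARLY LOW / EARLY HIGH session classification.

All tables are returned as tidy DataFrames with explicit event counts so
probabilities can be re-aggregated across sessions or subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task_env import REVERSAL_TRIAL, Session

AKB_BINS = ("1", "2", "3", "4-7")
NOT_REACHED = -1  # sentinel for trials_to_criterion


def _session_meta(s: Session) -> dict:
    return {
        "subject_id": s.subject_id,
        "group": s.group,
        "phase": s.phase,
        "schedule_kind": s.schedule.kind,
        "session_id": s.session_id,
    }


def switch_stay_table(
    sessions: Iterable[Session],
    split_reversal: bool = False,
) -> pd.DataFrame:
    """P(switch at n | outcome at n-1), per session.

    A switch is a choice differing from the previous trial's choice within
    the same session.  With ``split_reversal`` the transitions are split
    into pre-reversal (current trial <= reversal) and post-reversal
    segments.
    """
    rows = []
    for s in sessions:
        ch, rw = s.choices, s.rewards
        if len(ch) < 2:
            continue
        n = np.arange(2, len(ch) + 1)  # 1-based index of the current trial
        switched = ch[1:] != ch[:-1]
        prev_rewarded = rw[:-1] == 1
        rev = s.schedule.reversal_trial
        if split_reversal and rev is not None:
            segments = {"pre_reversal": n <= rev, "post_reversal": n > rev}
        else:
            segments = {"all": np.ones(len(n), dtype=bool)}
        for seg_name, seg_mask in segments.items():
            for outcome, omask in (("reward", prev_rewarded), ("no_reward", ~prev_rewarded)):
                mask = seg_mask & omask
                n_events = int(mask.sum())
                rows.append(
                    {
                        **_session_meta(s),
                        "segment": seg_name,
                        "prior_outcome": outcome,
                        "n_events": n_events,
                        "n_switch": int(switched[mask].sum()),
                        "p_switch": float(switched[mask].mean()) if n_events else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def _akb_bin(run_len: int) -> str | None:
    if run_len <= 0:
        return None
    if run_len <= 3:
        return str(run_len)
    return "4-7"  # runs longer than 7 pooled here as well


def akb_event(choices: np.ndarray, n: int, *, max_run: int = 7, pool_long_runs: bool = True) -> tuple[int, int, int] | None:
    """Detect an A_kB event at (0-based) trial ``n``.

    The pattern requires: choice at n-1 is some option B; the trials
    immediately before it form a homogeneous run of one option A != B of
    length k (lags 2..max_run+1, so k <= ``max_run``); and A does not recur
    within the remainder of that lookback window (a mixed-identity history
    is not a clean run condition).  Runs longer than ``max_run`` are capped
    to it when ``pool_long_runs`` else rejected.  Returns (k, A, B) or None.
    """
    if n < 2:
        return None
    b = ch_b = choices[n - 1]
    a = choices[n - 2]
    if a == b:
        return None
    lo = max(0, n - 1 - max_run)  # lookback window: lags 2 .. max_run+1
    stretch = choices[lo : n - 1]  # oldest .. lag-2, run is a suffix
    k = 0
    t = len(stretch) - 1
    while t >= 0 and stretch[t] == a:
        k += 1
        t -= 1
    if t >= 0 and np.any(stretch[: t + 1] == a):
        return None  # A recurs before the run: mixed-identity history
    if k == len(stretch) and lo > 0 and choices[lo - 1] == a:
        # run extends beyond the lookback window
        if not pool_long_runs:
            return None
    return k, int(a), int(ch_b)


def akb_table(
    sessions: Iterable[Session],
    *,
    require_maximal: bool = True,
    pool_long_runs: bool = True,
) -> pd.DataFrame:
    """Next-choice probabilities after a run of A choices and a single B.

    An event at trial n requires: choice at n-1 is some option B, and the
    k trials before that (n-2 .. n-(k+1)) are all one option A != B, with A
    absent from the rest of the recent-history window (see
    :func:`akb_event`).  With ``require_maximal`` (default) each event falls
    in exactly one bin; without it, an event with a run of length k also
    counts toward every shorter-run bin (the "at least k" reading, under
    which A_1B does not check trial n-3).  k >= 4 is pooled into the "4-7"
    bin; runs longer than 7 are pooled there too unless ``pool_long_runs``
    is false.  Events are grouped by (run bin, B's outcome at n-1) and the
    next choice classed as B (repeat), A (revert) or C (the third option).
    """
    counts: dict[tuple[str, str], np.ndarray] = {}

    def record(bin_label: str, outcome: str, nxt: int, a: int, b: int) -> None:
        vec = counts.setdefault((bin_label, outcome), np.zeros(4))  # [n, B, A, C]
        vec[0] += 1
        if nxt == b:
            vec[1] += 1
        elif nxt == a:
            vec[2] += 1
        else:
            vec[3] += 1

    for s in sessions:
        ch, rw = s.choices, s.rewards
        for n in range(2, len(ch)):
            ev = akb_event(ch, n, pool_long_runs=pool_long_runs)
            if ev is None:
                continue
            k, a, b = ev
            outcome = "reward" if rw[n - 1] == 1 else "no_reward"
            if require_maximal:
                bins = [_akb_bin(k)]
            else:
                bins = list(dict.fromkeys(_akb_bin(kk) for kk in range(1, k + 1)))
            for bin_label in bins:
                if bin_label is not None:
                    record(bin_label, outcome, int(ch[n]), a, b)
    rows = []
    for (bin_label, outcome), (n_ev, nb, na, nc) in sorted(counts.items()):
        rows.append(
            {
                "condition": bin_label,
                "prior_outcome": outcome,
                "n_events": int(n_ev),
                "p_next_B": nb / n_ev,
                "p_next_A": na / n_ev,
                "p_next_C": nc / n_ev,
            }
        )
    return pd.DataFrame(rows)


def choice_frequency_table(sessions: Iterable[Session]) -> pd.DataFrame:
    """Repeat probability by how often the just-chosen option was picked recently.

    For every trial n with at least six predecessors, let B be the choice at
    n-1; the condition is the count of B choices over trials n-2 .. n-6
    (0-5) crossed with B's outcome at n-1; the outcome measure is
    P(choice at n = B).
    """
    counts: dict[tuple[int, str], np.ndarray] = {}
    for s in sessions:
        ch, rw = s.choices, s.rewards
        for n in range(6, len(ch)):
            b = ch[n - 1]
            freq = int(np.sum(ch[n - 6 : n - 1] == b))
            outcome = "reward" if rw[n - 1] == 1 else "no_reward"
            vec = counts.setdefault((freq, outcome), np.zeros(2))
            vec[0] += 1
            vec[1] += ch[n] == b
    rows = []
    for (freq, outcome), (n_ev, n_rep) in sorted(counts.items()):
        rows.append(
            {
                "condition": freq,
                "prior_outcome": outcome,
                "n_events": int(n_ev),
                "p_repeat": n_rep / n_ev,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CriterionResult:
    per_session: pd.DataFrame  # columns: session meta + criterion_trial
    per_subject: pd.DataFrame  # subject_id, group, median_criterion_trial


def trials_to_criterion(
    sessions: Sequence[Session],
    labels: Sequence[np.ndarray],
    *,
    threshold: float = 0.65,
    window: int = 20,
    segment: str = "acquisition",
) -> CriterionResult:
    """First trial at which best-option choices reach criterion.

    The criterion is met at the first trial t whose trailing ``window``
    trials (within the segment) contain at least ``threshold`` best-option
    choices.  ``segment='post_reversal'`` starts counting at the trial after
    the reversal; the returned trial index is 1-based within the segment.
    Sessions that never reach criterion get the sentinel ``NOT_REACHED``;
    subject summaries are medians over sessions (sentinels excluded).
    """
    rows = []
    for s, lab in zip(sessions, labels):
        correct = (s.choices == np.asarray(lab)).astype(float)
        rev = s.schedule.reversal_trial
        if segment == "acquisition":
            seg = correct[: rev if rev is not None else len(correct)]
        elif segment == "post_reversal":
            if rev is None:
                continue
            seg = correct[rev:]
        else:
            raise ValueError(f"segment must be 'acquisition' or 'post_reversal', got {segment!r}")
        crit = NOT_REACHED
        if len(seg) >= window:
            frac = pd.Series(seg).rolling(window).mean().to_numpy()
            hits = np.flatnonzero(frac >= threshold)
            if hits.size:
                crit = int(hits[0]) + 1  # 1-based within segment
        rows.append({**_session_meta(s), "criterion_trial": crit})
    per_session = pd.DataFrame(rows)
    reached = per_session[per_session["criterion_trial"] != NOT_REACHED]
    per_subject = (
        reached.groupby(["subject_id", "group"], as_index=False)["criterion_trial"]
        .median()
        .rename(columns={"criterion_trial": "median_criterion_trial"})
    )
    return CriterionResult(per_session=per_session, per_subject=per_subject)


def v1_choice_summary(
    sessions: Sequence[Session],
    labels: Sequence[np.ndarray],
    *,
    halves: bool = True,
    ex_v1_window: int | None = None,
) -> pd.DataFrame:
    """Per-session proportion of best-option choices, whole and by half.

    With ``ex_v1_window`` set (e.g. 50), adds the proportion of choices of
    the pre-reversal best option over that many trials after the reversal —
    a perseveration measure.
    """
    rows = []
    for s, lab in zip(sessions, labels):
        lab = np.asarray(lab)
        correct = s.choices == lab
        row = {**_session_meta(s), "p_v1": float(correct.mean())}
        rev = s.schedule.reversal_trial
        if halves:
            half = rev if rev is not None else len(correct) // 2
            row["p_v1_first_half"] = float(correct[:half].mean())
            row["p_v1_second_half"] = float(correct[half:].mean()) if len(correct) > half else np.nan
        if ex_v1_window is not None and rev is not None:
            ex_v1 = lab[rev - 1]  # best option just before the reversal
            post = s.choices[rev : rev + ex_v1_window]
            row["p_ex_v1_post"] = float(np.mean(post == ex_v1)) if len(post) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def latency_summary(sessions: Iterable[Session]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stay/switch mean log latencies per subject, plus a 100 ms histogram.

    Latencies are natural-log transformed; the first trial of each session
    has no stay/switch status and is excluded from the stay/switch means but
    included in the histogram.  Non-positive latencies are rejected.
    """
    per_trial = []
    all_latencies = []
    for s in sessions:
        lat = s.latencies_ms
        if np.any(lat <= 0):
            raise ValueError(f"non-positive latency in session {s.session_id} of {s.subject_id}")
        ch = s.choices
        all_latencies.append(lat)
        for n in range(1, len(ch)):
            per_trial.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "phase": s.phase,
                    "transition": "switch" if ch[n] != ch[n - 1] else "stay",
                    "log_latency": np.log(lat[n]),
                }
            )
    df = pd.DataFrame(per_trial)
    summary = (
        df.groupby(["subject_id", "group", "phase", "transition"], as_index=False)["log_latency"]
        .agg(mean_log_latency="mean", n_trials="size")
    )
    lat_all = np.concatenate(all_latencies) if all_latencies else np.array([])
    edges = np.arange(0, (np.max(lat_all) // 100 + 2) * 100, 100) if lat_all.size else np.array([0, 100])
    hist, _ = np.histogram(lat_all, bins=edges)
    hist_df = pd.DataFrame(
        {"bin_left_ms": edges[:-1].astype(int), "bin_right_ms": edges[1:].astype(int), "count": hist}
    )
    return summary, hist_df


def fixed_early_late(
    sessions: Sequence[Session],
    labels: Sequence[np.ndarray],
    *,
    low_thresh: float = 0.25,
    high_thresh: float = 0.75,
    window: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify fixed-schedule sessions by early best-option performance.

    Sessions whose first-``window`` best-option proportion is <=
    ``low_thresh`` are EARLY_LOW, >= ``high_thresh`` EARLY_HIGH (both
    inclusive), otherwise neither.  Returns the per-session table and a
    group-level summary with median endpoints and a two-sample
    Kolmogorov-Smirnov comparison of endpoint distributions between groups
    within each class.
    """
    rows = []
    for s, lab in zip(sessions, labels):
        if s.n_trials < 2 * window:
            raise ValueError("sessions must have at least 2 * window trials")
        correct = s.choices == np.asarray(lab)
        early = float(correct[:window].mean())
        late = float(correct[-window:].mean())
        if early <= low_thresh:
            cls = "EARLY_LOW"
        elif early >= high_thresh:
            cls = "EARLY_HIGH"
        else:
            cls = "neither"
        rows.append({**_session_meta(s), "p_v1_early": early, "p_v1_late": late, "early_class": cls})
    per_session = pd.DataFrame(rows)

    summary_rows = []
    for cls in ("EARLY_LOW", "EARLY_HIGH"):
        sub = per_session[per_session["early_class"] == cls]
        groups = sorted(sub["group"].unique())
        meds = {g: float(sub.loc[sub["group"] == g, "p_v1_late"].median()) for g in groups}
        ks_p = np.nan
        if len(groups) == 2:
            a = sub.loc[sub["group"] == groups[0], "p_v1_late"]
            b = sub.loc[sub["group"] == groups[1], "p_v1_late"]
            if len(a) and len(b):
                ks_p = float(stats.ks_2samp(a, b).pvalue)
        for g in groups:
            n_g = int((sub["group"] == g).sum())
            summary_rows.append(
                {"early_class": cls, "group": g, "n_sessions": n_g, "median_p_v1_late": meds[g], "ks_pvalue": ks_p}
            )
    return per_session, pd.DataFrame(summary_rows)
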