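"""End-to-end cohort report: run every analysis and emit a table directory.

:func:`run_report` takes a set of sessions (typically a simulated cohort)
and produces one directory of tidy TSV tables grouped by analysis family:

* ``fig3_performance`` — best-option choice proportions, trials to
  criterion (acquisition and post-reversal) and the latency histogram;
* ``fig4_switching``   — outcome-conditioned switch probabilities split at
  the reversal, and stay/switch log-latency means;
* ``fig5_history``     — A_kB run-history and choice-frequency tables per
  group x phase;
* ``fig6_kernel``      — per subject x phase lagged choice x outcome
  kernels, combined grids and their contingent/spread partitions;
* ``fig7_fixed``       — EARLY LOW / EARLY HIGH classification of
  fixed-schedule sessions;

plus per-subject learning-rate fits (``rl_fits.tsv``) and a machine-readable
``run_log.yaml``.  Stages are independent: a failure in one is recorded in
the log and the rest still run.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kernel import COLUMN_LAGS, INTEREST_MASK, fit_history_kernel, partition_kernel
from .metrics import (
    akb_table,
    choice_frequency_table,
    fixed_early_late,
    latency_summary,
    switch_stay_table,
    trials_to_criterion,
    v1_choice_summary,
)
from .rl import fit_learning_rate
from .task_env import Session, v1_sch_labels


def kernel_long_frame(result, subject_id: str, phase: str) -> pd.DataFrame:
    rows = []
    for fit in result.per_stimulus:
        se = np.sqrt(np.diag(fit.cov))
        for k, (i, j) in enumerate(COLUMN_LAGS):
            rows.append(
                {
                    "subject_id": subject_id,
                    "phase": phase,
                    "target": fit.target,
                    "choice_lag": i,
                    "outcome_lag": j,
                    "beta": fit.beta[k],
                    "se": se[k],
                    "interest": bool(INTEREST_MASK[k]),
                    "ridged": fit.ridged,
                }
            )
    for k, (i, j) in enumerate(COLUMN_LAGS):
        rows.append(
            {
                "subject_id": subject_id,
                "phase": phase,
                "target": "combined",
                "choice_lag": i,
                "outcome_lag": j,
                "beta": result.combined_beta[k],
                "se": np.nan,
                "interest": bool(INTEREST_MASK[k]),
                "ridged": any(f.ridged for f in result.per_stimulus),
            }
        )
    return pd.DataFrame(rows)


def run_report(
    sessions: Sequence[Session],
    out_dir: str | Path,
    *,
    fit_rl: bool = True,
    fallback_alpha: float = 0.3,
    criterion_threshold: float = 0.65,
    criterion_window: int = 20,
    seed: int | None = None,
) -> dict:
    """Run the full analysis battery and write one TSV per table.

    Returns a manifest dict (also written as ``run_log.yaml``) listing the
    emitted tables, the parameters used, and any stage failures.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = list(sessions)
    varying = [s for s in sessions if s.schedule.is_varying]
    fixed = [s for s in sessions if not s.schedule.is_varying]
    labels_v = [v1_sch_labels(s.schedule) for s in varying]
    labels_f = [v1_sch_labels(s.schedule) for s in fixed]

    log: dict = {
        "revlearn_version": __version__,
        "n_sessions": len(sessions),
        "seed": seed,
        "parameters": {
            "criterion_threshold": criterion_threshold,
            "criterion_window": criterion_window,
            "fallback_alpha": fallback_alpha,
            "fit_rl": fit_rl,
        },
        "tables": [],
        "failures": [],
    }

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        log["tables"].append(str(path.name))

    def stage(name: str, fn) -> None:
        try:
            fn()
        except Exception as exc:  # keep independent stages running
            log["failures"].append({"stage": name, "error": f"{type(exc).__name__}: {exc}"})

    # --- learning-rate fits (pre-phase varying sessions, per subject)
    alpha_by_subject: dict[str, float] = {}

    def _fit_rl() -> None:
        rows = []
        by_subject: dict[str, list[Session]] = {}
        for s in varying:
            if s.phase == "pre":
                by_subject.setdefault(s.subject_id, []).append(s)
        if not by_subject:
            log["failures"].append(
                {"stage": "fit_rl", "error": "no pre-phase sessions: using fallback alpha"}
            )
        for subject, subj_sessions in sorted(by_subject.items()):
            fit = fit_learning_rate(subj_sessions)
            alpha_by_subject[subject] = fit.alpha_hat
            rows.append(
                {
                    "subject_id": subject,
                    "alpha_hat": fit.alpha_hat,
                    "beta_sm_hat": fit.beta_sm_hat,
                    "neg_log_likelihood": fit.neg_log_likelihood,
                    "converged": fit.converged,
                    "boundary": fit.boundary,
                    "n_trials": fit.n_trials,
                }
            )
        if rows:
            emit("rl_fits", pd.DataFrame(rows))

    if fit_rl:
        stage("fit_rl", _fit_rl)

    # --- fig3: performance, criterion, latency histogram
    def _fig3() -> None:
        emit(
            "fig3_performance",
            v1_choice_summary(varying, labels_v, halves=True, ex_v1_window=50),
        )
        for segment in ("acquisition", "post_reversal"):
            res = trials_to_criterion(
                varying,
                labels_v,
                threshold=criterion_threshold,
                window=criterion_window,
                segment=segment,
            )
            emit(f"fig3_criterion_{segment}", res.per_session)
            emit(f"fig3_criterion_{segment}_by_subject", res.per_subject)
        _, hist = latency_summary(varying)
        emit("fig3_latency_hist", hist)

    if varying:
        stage("fig3", _fig3)

    # --- fig4: switching and stay/switch latencies
    def _fig4() -> None:
        emit("fig4_switching", switch_stay_table(varying, split_reversal=True))
        summary, _ = latency_summary(varying)
        emit("fig4_latency_stay_switch", summary)

    if varying:
        stage("fig4", _fig4)

    # --- fig5: history tables per group x phase
    def _fig5() -> None:
        akb_rows, freq_rows = [], []
        cells = sorted({(s.group, s.phase) for s in varying})
        for group, phase in cells:
            cell = [s for s in varying if s.group == group and s.phase == phase]
            t = akb_table(cell)
            t.insert(0, "group", group)
            t.insert(1, "phase", phase)
            akb_rows.append(t)
            t = choice_frequency_table(cell)
            t.insert(0, "group", group)
            t.insert(1, "phase", phase)
            freq_rows.append(t)
        emit("fig5_akb", pd.concat(akb_rows, ignore_index=True))
        emit("fig5_choice_frequency", pd.concat(freq_rows, ignore_index=True))

    if varying:
        stage("fig5", _fig5)

    # --- fig6: history kernels per subject x phase
    def _fig6() -> None:
        frames, part_rows = [], []
        cells = sorted({(s.subject_id, s.phase) for s in varying})
        for subject, phase in cells:
            cell = [s for s in varying if s.subject_id == subject and s.phase == phase]
            result = fit_history_kernel(cell)
            frames.append(kernel_long_frame(result, subject, phase))
            parts = partition_kernel(result.grid)
            meta = next(s for s in varying if s.subject_id == subject)
            for lag in range(5):
                part_rows.append(
                    {
                        "subject_id": subject,
                        "group": meta.group,
                        "phase": phase,
                        "lag": lag + 1,
                        "contingent": parts["contingent"][lag],
                        "choice_lag_mean": parts["choice_lag_mean"][lag],
                        "outcome_lag_mean": parts["outcome_lag_mean"][lag],
                    }
                )
        emit("fig6_kernel", pd.concat(frames, ignore_index=True))
        emit("fig6_kernel_partition", pd.DataFrame(part_rows))

    if varying:
        stage("fig6", _fig6)

    # --- fig7: fixed-schedule EARLY LOW / HIGH
    def _fig7() -> None:
        per_session, summary = fixed_early_late(fixed, labels_f)
        emit("fig7_fixed_sessions", per_session)
        emit("fig7_fixed_summary", summary)

    if fixed:
        stage("fig7", _fig7)

    with (out / "run_log.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    return log
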