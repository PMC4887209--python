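"""Rescorla-Wagner value learning with Boltzmann (softmax) choice.

The model maintains one value per option; after each trial only the chosen
option's value moves toward the obtained outcome:

    V_{t+1}(c) = V_t(c) + alpha * (r_t - V_t(c))

and choice probabilities are softmax in the values with inverse temperature
``beta_sm``:  P(c) ∝ exp(beta_sm * V(c)).

A learning rate (and optionally the inverse temperature) is fitted per
subject by maximum likelihood over that subject's sessions, with values
reset at each session start because every session uses novel stimuli.  The
fitted model also yields per-trial "subjectively best option" labels
(``V1_RL``): the argmax of the forward-simulated values given the subject's
actual choices and outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .task_env import N_OPTIONS, Session

DEFAULT_INIT_VALUE = 1.0 / 3.0
ALPHA_BOUNDS = (1e-4, 1.0)
BETA_BOUNDS = (1e-3, 50.0)
#: multi-start grid for the likelihood optimizer
ALPHA_STARTS = (0.05, 0.2, 0.5, 0.8)
BETA_STARTS = (1.0, 4.0, 12.0)


@dataclass
class FitResult:
    alpha_hat: float
    beta_sm_hat: float
    neg_log_likelihood: float
    converged: bool
    n_trials: int
    fit_beta: bool
    boundary: bool = False
    starts_tried: int = 0
    messages: list[str] = field(default_factory=list)


def rw_update(value: float, reward: int, alpha: float) -> float:
    """One delta-rule step: V + alpha * (reward - V)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return value + alpha * (reward - value)


def softmax_probs(values: np.ndarray | Sequence[float], beta_sm: float) -> np.ndarray:
    """Boltzmann choice probabilities, computed with max-subtraction."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if beta_sm < 0:
        raise ValueError(f"beta_sm must be >= 0, got {beta_sm}")
    z = beta_sm * v
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def value_trace(
    choices: np.ndarray,
    rewards: np.ndarray,
    alpha: float,
    init_value: float = DEFAULT_INIT_VALUE,
) -> np.ndarray:
    """Forward-simulated option values *before* each trial's choice (T x 3)."""
    T = len(choices)
    out = np.empty((T, N_OPTIONS))
    v = np.full(N_OPTIONS, init_value, dtype=float)
    for t in range(T):
        out[t] = v
        c = choices[t]
        v[c] = v[c] + alpha * (rewards[t] - v[c])
    return out


def _stacked_nll(
    choices: np.ndarray,  # T x S
    rewards: np.ndarray,  # T x S
    alpha: float,
    beta_sm: float,
    init_value: float,
) -> float:
    """NLL over S equal-length sessions, iterated over trials jointly."""
    T, S = choices.shape
    v = np.full((S, N_OPTIONS), init_value, dtype=float)
    sidx = np.arange(S)
    nll = 0.0
    for t in range(T):
        z = beta_sm * v
        z -= z.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        c = choices[t]
        nll -= logp[sidx, c].sum()
        v[sidx, c] += alpha * (rewards[t] - v[sidx, c])
    return float(nll)


def session_nll(
    sessions: Iterable[Session],
    alpha: float,
    beta_sm: float,
    init_value: float = DEFAULT_INIT_VALUE,
) -> float:
    """Summed negative log likelihood of the observed choices.

    Values reset at every session start.  Returns ``+inf`` (never raises)
    when a degenerate parameterization assigns an observed choice zero
    probability.
    """
    sessions = list(sessions)
    if not sessions or any(s.n_trials == 0 for s in sessions):
        raise ValueError("sessions must be non-empty")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if beta_sm < 0:
        raise ValueError(f"beta_sm must be >= 0, got {beta_sm}")
    # group equal-length sessions so the trial loop runs once per group
    by_len: dict[int, list[Session]] = {}
    for s in sessions:
        by_len.setdefault(s.n_trials, []).append(s)
    total = 0.0
    for length, group in by_len.items():
        ch = np.column_stack([s.choices for s in group])
        rw = np.column_stack([s.rewards for s in group])
        total += _stacked_nll(ch, rw, alpha, beta_sm, init_value)
    if not np.isfinite(total):
        return float("inf")
    return total


def fit_learning_rate(
    sessions: Iterable[Session],
    *,
    fit_beta: bool = True,
    fixed_beta: float = 5.0,
    init_value: float = DEFAULT_INIT_VALUE,
) -> FitResult:
    """Maximum-likelihood fit of alpha (and optionally beta_sm).

    Runs L-BFGS-B from a grid of starting points and returns the best
    optimum.  If no start converges the best point found is still returned,
    flagged via ``converged=False``; estimates pinned at a parameter bound
    are flagged via ``boundary=True``.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("sessions must be non-empty")
    n_trials = sum(s.n_trials for s in sessions)

    if fit_beta:
        def objective(x: np.ndarray) -> float:
            return session_nll(sessions, x[0], x[1], init_value)

        bounds = [ALPHA_BOUNDS, BETA_BOUNDS]
        starts = [(a, b) for a in ALPHA_STARTS for b in BETA_STARTS]
    else:
        def objective(x: np.ndarray) -> float:
            return session_nll(sessions, x[0], fixed_beta, init_value)

        bounds = [ALPHA_BOUNDS]
        starts = [(a,) for a in ALPHA_STARTS]

    best = None
    any_converged = False
    messages: list[str] = []
    for x0 in starts:
        res = optimize.minimize(objective, np.array(x0), method="L-BFGS-B", bounds=bounds)
        any_converged = any_converged or bool(res.success)
        if not res.success:
            messages.append(f"start {x0}: {res.message}")
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    alpha_hat = float(best.x[0])
    beta_hat = float(best.x[1]) if fit_beta else float(fixed_beta)
    tol = 1e-6
    boundary = (
        alpha_hat <= ALPHA_BOUNDS[0] + tol
        or alpha_hat >= ALPHA_BOUNDS[1] - tol
        or (fit_beta and (beta_hat <= BETA_BOUNDS[0] + tol or beta_hat >= BETA_BOUNDS[1] - tol))
    )
    return FitResult(
        alpha_hat=alpha_hat,
        beta_sm_hat=beta_hat,
        neg_log_likelihood=float(best.fun),
        converged=any_converged,
        n_trials=n_trials,
        fit_beta=fit_beta,
        boundary=boundary,
        starts_tried=len(starts),
        messages=messages,
    )


def v1_rl_labels(
    session: Session,
    alpha: float,
    init_value: float = DEFAULT_INIT_VALUE,
) -> np.ndarray:
    """Subjectively best option per trial under the fitted learner.

    Argmax of the pre-choice forward-simulated values given the subject's
    actual choices and rewards; ties break to the lowest option index.
    """
    trace = value_trace(session.choices, session.rewards, alpha, init_value)
    return np.argmax(trace, axis=1)
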