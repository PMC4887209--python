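"""Lagged choice x outcome logistic-regression credit-assignment kernel.

For each stimulus (target) in turn, a binary logistic regression predicts
whether the target was chosen on trial n from every combination of the
choice made i trials ago and the outcome received j trials ago
(i, j = 1..6).  Each explanatory variable (EV) is coded

    +1  if trial n-j was rewarded and the choice at n-i was the target,
    -1  if trial n-j was rewarded and the choice at n-i was another option,
     0  if trial n-j was unrewarded,

giving 36 EVs: the 25 combinations with i <= 5 and j <= 5 are the EVs of
interest, and the 11 with i = 6 or j = 6 are confounds absorbing longer
choice/reward trends.  The three per-stimulus coefficient vectors are
combined by their inverse-covariance (variance-weighted) mean:

    beta = (C_A^-1 + C_B^-1 + C_C^-1)^-1 (C_A^-1 b_A + C_B^-1 b_B + C_C^-1 b_C)

The combined 5x5 interest grid splits into contingent learning (the i = j
diagonal: credit assigned to the choice that produced the outcome) and two
spread-of-effect components: past outcomes spreading forward onto more
recent choices (i < j) and recent outcomes spreading backward onto earlier
choices (i > j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .task_env import N_OPTIONS, Session

MAX_LAG = 6
INTEREST_LAG = 5
N_EV = MAX_LAG * MAX_LAG  # 36
#: (choice_lag, outcome_lag) for every column, row-major in choice lag
COLUMN_LAGS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(1, MAX_LAG + 1) for j in range(1, MAX_LAG + 1)
)
INTEREST_MASK = np.array([(i <= INTEREST_LAG and j <= INTEREST_LAG) for i, j in COLUMN_LAGS])
N_INTEREST = int(INTEREST_MASK.sum())  # 25
N_CONFOUND = N_EV - N_INTEREST  # 11

#: ridge strength applied to the slopes when the plain fit separates
RIDGE_PENALTY = 1e-2


@dataclass
class DesignMatrix:
    X: np.ndarray  # N x 36, entries in {-1, 0, +1}
    y: np.ndarray  # N, 0/1: chose the target
    target: int
    column_lags: tuple[tuple[int, int], ...] = COLUMN_LAGS
    interest_mask: np.ndarray = field(default_factory=lambda: INTEREST_MASK.copy())


@dataclass
class StimulusFit:
    beta: np.ndarray  # 36 slopes
    cov: np.ndarray  # 36 x 36
    intercept: float
    target: int
    ridged: bool = False
    rank_deficient_columns: tuple[int, ...] = ()


@dataclass
class KernelResult:
    per_stimulus: list[StimulusFit]
    combined_beta: np.ndarray  # 36

    @property
    def grid(self) -> np.ndarray:
        """5x5 interest weights indexed (choice lag - 1, outcome lag - 1)."""
        return beta_to_grid(self.combined_beta)


def lagged_features(
    choices: np.ndarray,
    rewards: np.ndarray,
    t: int,
    target: int,
) -> np.ndarray:
    """The 36-EV feature vector for trial index ``t`` (0-based, t >= 6)."""
    x = np.zeros(N_EV)
    for k, (i, j) in enumerate(COLUMN_LAGS):
        if rewards[t - j]:
            x[k] = 1.0 if choices[t - i] == target else -1.0
    return x


def build_design_matrix(sessions: Iterable[Session], target: int) -> DesignMatrix:
    """One row per trial with at least 6 predecessors in the same session.

    Rows never span session boundaries (each session uses novel stimuli, so
    there is no meaningful cross-session history).
    """
    if target not in range(N_OPTIONS):
        raise ValueError(f"target must be in 0..{N_OPTIONS - 1}, got {target}")
    rows: list[np.ndarray] = []
    ys: list[int] = []
    n_sessions = 0
    for session in sessions:
        n_sessions += 1
        ch, rw = session.choices, session.rewards
        for t in range(MAX_LAG, len(ch)):
            rows.append(lagged_features(ch, rw, t, target))
            ys.append(int(ch[t] == target))
    if n_sessions == 0:
        raise ValueError("sessions must be non-empty")
    if not rows:
        raise ValueError("no session long enough to contribute rows (need > 6 trials)")
    return DesignMatrix(X=np.array(rows), y=np.array(ys, dtype=int), target=target)


def _ridge_logit(Xc: np.ndarray, y: np.ndarray, penalty: float) -> tuple[np.ndarray, np.ndarray]:
    """L2-penalized logistic fit by Newton iteration; intercept unpenalized.

    Returns (params, covariance) with the covariance taken as the inverse
    penalized Hessian.
    """
    n, p = Xc.shape
    pen = np.full(p, penalty)
    pen[0] = 0.0  # intercept
    w = np.zeros(p)
    for _ in range(100):
        eta = Xc @ w
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Xc.T @ (y - mu) - pen * w
        W = mu * (1 - mu)
        H = (Xc * W[:, None]).T @ Xc + np.diag(pen)
        step = np.linalg.solve(H, grad)
        w = w + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = Xc @ w
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    H = (Xc * W[:, None]).T @ Xc + np.diag(pen)
    return w, np.linalg.inv(H)


def fit_stimulus_regression(
    dm: DesignMatrix,
    *,
    cov_type: str = "nonrobust",
    ridge_on_separation: bool = True,
) -> StimulusFit:
    """Maximum-likelihood logistic regression of y on the 36 EVs + intercept.

    The covariance is the inverse observed information by default
    (``cov_type='nonrobust'``); ``cov_type='HC0'`` gives the sandwich
    estimate.  Perfect or quasi-separation triggers a small documented ridge
    penalty on the slopes, flagged in the result, never applied silently.
    """
    X, y = dm.X, dm.y
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    rank_deficient: tuple[int, ...] = ()
    if rank < Xc.shape[1]:
        # report all-zero or duplicated EV columns (0-based EV indices)
        zero_cols = tuple(int(k) for k in np.flatnonzero(~X.any(axis=0)))
        rank_deficient = zero_cols if zero_cols else tuple(range(N_EV))

    model = sm.Logit(y, Xc)
    ridged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # PerfectSeparationWarning -> fallback
            res = model.fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params()) if cov_type == "nonrobust" else np.asarray(
            model.fit(disp=0, maxiter=200, cov_type=cov_type).cov_params()
        )
        bad = (
            not np.all(np.isfinite(params))
            or not np.all(np.isfinite(cov))
            or np.max(np.abs(params)) > 50
        )
    except Exception:
        bad = True
        params = cov = None  # type: ignore[assignment]
    if bad:
        if not ridge_on_separation:
            raise RuntimeError("logistic fit failed (separation?) and ridge fallback disabled")
        params, cov = _ridge_logit(Xc, y, RIDGE_PENALTY)
        ridged = True

    return StimulusFit(
        beta=params[1:].copy(),
        cov=cov[1:, 1:].copy(),
        intercept=float(params[0]),
        target=dm.target,
        ridged=ridged,
        rank_deficient_columns=rank_deficient,
    )


def combine_weights(
    betas: Sequence[np.ndarray],
    covs: Sequence[np.ndarray],
) -> np.ndarray:
    """Inverse-covariance-weighted mean of the per-stimulus coefficients."""
    if len(betas) != len(covs) or not betas:
        raise ValueError("need matching, non-empty beta/covariance sequences")
    dim = np.asarray(betas[0]).shape[0]
    precision_sum = np.zeros((dim, dim))
    weighted_sum = np.zeros(dim)
    for b, C in zip(betas, covs):
        b = np.asarray(b, dtype=float)
        C = np.asarray(C, dtype=float)
        if b.shape != (dim,) or C.shape != (dim, dim):
            raise ValueError("dimension mismatch between betas and covariances")
        try:
            P = np.linalg.inv(C)
        except np.linalg.LinAlgError:
            warnings.warn("singular covariance: using pseudo-inverse", RuntimeWarning)
            P = np.linalg.pinv(C)
        precision_sum += P
        weighted_sum += P @ b
    try:
        return np.linalg.solve(precision_sum, weighted_sum)
    except np.linalg.LinAlgError:
        warnings.warn("singular combined precision: using pseudo-inverse", RuntimeWarning)
        return np.linalg.pinv(precision_sum) @ weighted_sum


def fit_history_kernel(
    sessions: Iterable[Session],
    *,
    cov_type: str = "nonrobust",
) -> KernelResult:
    """Per-stimulus design + fit + inverse-covariance combination, end to end."""
    sessions = list(sessions)
    fits = [
        fit_stimulus_regression(build_design_matrix(sessions, target), cov_type=cov_type)
        for target in range(N_OPTIONS)
    ]
    combined = combine_weights([f.beta for f in fits], [f.cov for f in fits])
    return KernelResult(per_stimulus=fits, combined_beta=combined)


def beta_to_grid(beta: np.ndarray) -> np.ndarray:
    """Extract the 5x5 interest grid (choice lag x outcome lag) from a 36-vector."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (N_EV,):
        raise ValueError(f"expected a {N_EV}-vector, got shape {beta.shape}")
    grid = np.empty((INTEREST_LAG, INTEREST_LAG))
    for k, (i, j) in enumerate(COLUMN_LAGS):
        if i <= INTEREST_LAG and j <= INTEREST_LAG:
            grid[i - 1, j - 1] = beta[k]
    return grid


def partition_kernel(grid_or_beta: np.ndarray) -> dict:
    """Split the interest grid into contingent and spread-of-effect parts.

    Returns per-lag contingent weights (the diagonal, 5 cells), the i < j
    choice-spread cells (10: past outcomes credited to more recent choices)
    and the i > j outcome-spread cells (10: recent outcomes credited to
    earlier choices), plus per-lag summaries averaging each choice lag over
    unrelated outcome lags and vice versa.
    """
    g = np.asarray(grid_or_beta, dtype=float)
    if g.shape == (N_EV,):
        g = beta_to_grid(g)
    if g.shape != (INTEREST_LAG, INTEREST_LAG):
        raise ValueError(f"expected a 5x5 grid or 36-vector, got shape {g.shape}")
    iu = np.triu_indices(INTEREST_LAG, k=1)  # i < j
    il = np.tril_indices(INTEREST_LAG, k=-1)  # i > j
    off = ~np.eye(INTEREST_LAG, dtype=bool)
    return {
        "contingent": np.diag(g).copy(),
        "choice_spread": g[iu].copy(),
        "outcome_spread": g[il].copy(),
        "choice_lag_mean": np.array([g[i, off[i]].mean() for i in range(INTEREST_LAG)]),
        "outcome_lag_mean": np.array([g[off[:, j], j].mean() for j in range(INTEREST_LAG)]),
    }


def recency_contrast(grid_or_beta: np.ndarray, mode: str = "with_n1") -> tuple[float, float]:
    """Recent vs distant choice weight at outcome lag 1.

    ``with_n1`` averages choice lags {1, 2}; ``noncontingent_only`` averages
    {2, 3} (excluding the lag-1 contingent cell); both compare against
    choice lags {4, 5}.
    """
    g = np.asarray(grid_or_beta, dtype=float)
    if g.shape == (N_EV,):
        g = beta_to_grid(g)
    if g.shape != (INTEREST_LAG, INTEREST_LAG):
        raise ValueError(f"expected a 5x5 grid or 36-vector, got shape {g.shape}")
    row = g[:, 0]  # outcome lag 1, indexed by choice lag
    if mode == "with_n1":
        recent = row[[0, 1]].mean()
    elif mode == "noncontingent_only":
        recent = row[[1, 2]].mean()
    else:
        raise ValueError(f"mode must be 'with_n1' or 'noncontingent_only', got {mode!r}")
    distant = row[[3, 4]].mean()
    return float(recent), float(distant)
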