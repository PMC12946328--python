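"""Closed-form maximum-likelihood estimation of influence weights.

Under the Gaussian posterior-confidence model, the log-likelihood of member
j's weight vector ``k_j`` given N trials is (up to constants) the negative
sum of squared residuals ``(C^p_{j,n} - k_j . C_n)^2``.  Its maximiser
solves the 3x3 normal-equation system

    ( sum_n C_n C_n^T ) k_j  =  sum_n C_n C^p_{j,n}

where ``C_n`` is the trial-n vector of the three prior log-odds.  Because
all members of a triad share the same priors within a condition, one Gram
matrix serves all three members.  The residual scale is estimated as the
Gaussian MLE ``sigma_hat = sqrt(RSS / N)``.

Near-singular systems (e.g. priors confined to a line) are solved by the
minimum-norm least-squares solution and flagged ``converged=False`` instead
of raising, so resampling procedures never abort; the Gram condition number
is always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision import MEMBERS, WeightVector

__all__ = [
    "EstimationResult",
    "InsufficientDataError",
    "estimate_weights",
    "fit_dataset",
    "flag_negative_weights",
    "solve_weights",
    "WEIGHT_COLUMNS",
]

#: Condition-number threshold above which the Gram system is treated as singular.
COND_LIMIT = 1e10

#: Column schema of a fitted-weights table.
WEIGHT_COLUMNS = [
    "group", "member", "condition", "k_a", "k_b", "k_c",
    "sigma", "n_trials", "converged", "gram_condition",
]

PRIOR_COLS = ["C_a", "C_b", "C_c"]
POST_COLS = ["Cp_a", "Cp_b", "Cp_c"]


class InsufficientDataError(ValueError):
    """Fewer trials than weight parameters to estimate."""


@dataclass
class EstimationResult:
    """A solved weight system plus conditioning diagnostics."""

    weights: WeightVector
    gram_condition: float
    converged: bool


def solve_weights(X: np.ndarray, y: np.ndarray):
    """Solve the normal equations for one or more members sharing priors.

    Parameters
    ----------
    X : ndarray, shape (n, 3)
        Prior log-odds (design matrix).
    y : ndarray, shape (n,) or (n, m)
        Posterior log-odds of one member, or of m members as columns.

    Returns
    -------
    k : ndarray, shape (3,) or (3, m)
    sigma : float or ndarray of shape (m,) — RMS residual per member
    gram_condition : float
    converged : bool
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise InsufficientDataError(f"need at least 3 trials to estimate 3 weights, got {n}")
    gram = X.T @ X
    xty = X.T @ y
    cond = float(np.linalg.cond(gram))
    if np.isfinite(cond) and cond < COND_LIMIT:
        k = np.linalg.solve(gram, xty)
        converged = True
    else:
        k, *_ = np.linalg.lstsq(X, y, rcond=None)
        converged = False
    resid = y - X @ k
    sigma = np.sqrt(np.mean(np.square(resid), axis=0))
    return k, sigma, cond, converged


def estimate_weights(trials: pd.DataFrame, member: str, condition: str | None = None) -> EstimationResult:
    """Estimate one member's weight vector from a wide trial table.

    ``trials`` must carry columns ``C_a, C_b, C_c`` (prior log-odds) and
    ``Cp_<member>`` (the member's posterior log-odds); pass ``condition`` to
    subset on the ``condition`` column first.
    """
    if member not in MEMBERS:
        raise ValueError(f"member must be one of {MEMBERS}, got {member!r}")
    df = trials if condition is None else trials[trials["condition"] == condition]
    X = df[PRIOR_COLS].to_numpy(dtype=float)
    y = df[f"Cp_{member}"].to_numpy(dtype=float)
    k, sigma, cond, converged = solve_weights(X, y)
    w = WeightVector(owner=member, k=k, sigma=float(sigma), n_trials=len(df))
    return EstimationResult(weights=w, gram_condition=cond, converged=converged)


def fit_dataset(trials: pd.DataFrame, by_list: bool = False) -> pd.DataFrame:
    """Fit every (group, member, condition[, list]) weight vector.

    One fit per participant per condition by default, pooling all of that
    condition's trials (lists combined); ``by_list=True`` fits each list
    separately instead.  Participants missing a condition are skipped with a
    console warning rather than failing the whole dataset.

    Returns
    -------
    DataFrame with columns ``WEIGHT_COLUMNS`` (plus ``list`` if by_list).
    """
    keys = ["group", "condition"] + (["list"] if by_list else [])
    rows = []
    for key_vals, sub in trials.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        X = sub[PRIOR_COLS].to_numpy(dtype=float)
        Y = sub[POST_COLS].to_numpy(dtype=float)
        k, sigma, cond, converged = solve_weights(X, Y)
        for m_idx, member in enumerate(MEMBERS):
            row = dict(zip(keys, key_vals))
            row.update(
                member=member,
                k_a=k[0, m_idx], k_b=k[1, m_idx], k_c=k[2, m_idx],
                sigma=float(sigma[m_idx]), n_trials=len(sub),
                converged=converged, gram_condition=cond,
            )
            rows.append(row)
    cols = WEIGHT_COLUMNS + (["list"] if by_list else [])
    out = pd.DataFrame(rows)
    return out[[c for c in cols if c in out.columns]]


def weights_as_matrix(weights: pd.DataFrame, group, condition) -> np.ndarray:
    """Extract a (3, 3) array of one triad-condition's weights, rows=members a,b,c."""
    sub = weights[(weights["group"] == group) & (weights["condition"] == condition)]
    sub = sub.set_index("member").loc[list(MEMBERS)]
    return sub[["k_a", "k_b", "k_c"]].to_numpy(dtype=float)


def flag_negative_weights(weights: pd.DataFrame, threshold: float = 0.0,
                          large: float = -0.1) -> pd.DataFrame:
    """Flag fitted weight vectors with negative components.

    Components in ``(large, threshold)`` get a ``minor_negative`` flag
    (plausible statistical anomalies near zero); components at or below
    ``large`` get ``large_negative``, the criterion used to nominate
    potential outlier groups for sensitivity reruns.
    """
    K = weights[["k_a", "k_b", "k_c"]].to_numpy(dtype=float)
    min_comp = K.min(axis=1)
    out = weights[["group", "member", "condition"]].copy()
    out["min_component"] = min_comp
    out["minor_negative"] = (min_comp < threshold) & (min_comp > large)
    out["large_negative"] = min_comp <= large
    return out
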