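"""Generative model of posterior confidence in a triad.

Each member ``j`` of a three-member group holds an influence weight vector
``k_j = (k_{j,a}, k_{j,b}, k_{j,c})`` over the group (including themselves).
After the discussion, member ``j``'s posterior log-odds confidence is
modelled as a noisy weighted sum of the three prior log-odds confidences:

    C_j^p ~ Normal( sum_i k_{j,i} * C_i,  sigma )

with ``sigma`` a standard deviation shared across members and trials, and
each member's noise drawn independently within a trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MEMBERS", "WeightVector", "posterior_mean", "simulate_posterior", "simulate_trial_set"]

#: Canonical member labels, in axis order.
MEMBERS = ("a", "b", "c")


@dataclass
class WeightVector:
    """One member's estimated (or true) influence weights.

    Attributes
    ----------
    owner : str
        The member this vector belongs to ("a", "b" or "c").
    k : ndarray, shape (3,)
        Weights toward members a, b, c in that order.
    sigma : float
        Residual standard deviation on the log-odds scale.
    n_trials : int
        Number of trials behind the estimate (0 for a specified truth).
    """

    owner: str
    k: np.ndarray
    sigma: float = 0.0
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.owner not in MEMBERS:
            raise ValueError(f"owner must be one of {MEMBERS}, got {self.owner!r}")
        self.k = np.asarray(self.k, dtype=float)
        if self.k.shape != (3,):
            raise ValueError(f"k must have shape (3,), got {self.k.shape}")
        if not np.all(np.isfinite(self.k)):
            raise ValueError("weight components must be finite")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def posterior_mean(prior, w) -> float:
    """Noiseless posterior log-odds: the weighted sum ``k . C``.

    ``prior`` is the length-3 vector of prior log-odds (a, b, c order);
    ``w`` may be a :class:`WeightVector` or a bare length-3 array.
    """
    k = w.k if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (3,) or k.shape != (3,):
        raise ValueError("prior and weights must be length-3 vectors")
    return float(prior @ k)


def simulate_posterior(prior, w, sigma: float, rng: np.random.Generator) -> float:
    """Draw one posterior log-odds confidence from the model."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    return posterior_mean(prior, w) + rng.normal(0.0, sigma)


def simulate_trial_set(priors, weights, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Simulate all three members' posteriors for a batch of trials.

    Parameters
    ----------
    priors : ndarray, shape (n_trials, 3)
        Prior log-odds per trial, columns in member order a, b, c.
    weights : mapping member -> WeightVector or length-3 array
        One weight vector per member; all three must be present.
    sigma : float
        Shared residual standard deviation.
    rng : numpy Generator

    Returns
    -------
    ndarray, shape (n_trials, 3)
        Posterior log-odds, columns in member order; each member's noise is
        independent within a trial.
    """
    priors = np.asarray(priors, dtype=float)
    if priors.ndim != 2 or priors.shape[1] != 3:
        raise ValueError("priors must have shape (n_trials, 3)")
    missing = [m for m in MEMBERS if m not in weights]
    if missing:
        raise ValueError(f"missing weight vectors for members: {missing}")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    K = np.column_stack(
        [np.asarray(weights[m].k if isinstance(weights[m], WeightVector) else weights[m], float)
         for m in MEMBERS]
    )  # (3 source, 3 member)
    means = priors @ K
    if sigma == 0:
        return means
    return means + rng.normal(0.0, sigma, size=means.shape)
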