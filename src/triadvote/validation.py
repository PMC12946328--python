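"""Simulation studies validating the estimator and the distance statistics.

Three studies, each fully reproducible from a config and a seed:

1. **Parameter recovery** — draw weight vectors with components uniform on
   (0.1, 1.5), simulate posteriors at sigma = 1, re-estimate, and compare
   estimated to true components at trial counts matching the subject, group
   and population scales of the study design (84, 252, 2520).
2. **Distance-metric validation** — extend recovery to the angular
   statistics, and check each against a sign-only *agreement index*
   computed from decisions alone: self-weighting against the fraction of
   trials where the posterior sign matches the member's own prior sign;
   weight equality against agreement with the equally-weighted sum; weight
   similarity / overall difference against sign agreement between two
   posterior sets generated from two independent weight draws.  Each
   distance should correlate negatively with its index.
3. **Reporting bias** — one member's *reported* prior log-odds are passed
   through a linear map C -> slope * C before estimation, while posteriors
   are generated from the unbiased values; sigma = 0.01 isolates the bias
   effect.  Underreporting (slope < 1) inflates the estimated weight toward
   the biased member, so other members' self-weighting distance is biased
   upward (their degree of self-weighting is underestimated); equality
   errors split into over- and under-estimation; pairwise-distance errors
   grow in variance with bias severity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import truncnorm

from .estimation import solve_weights
from .geometry import UNIFORM, angular_distance

__all__ = [
    "SimulationConfig",
    "BiasMap",
    "DEFAULT_BIAS_SETTINGS",
    "sample_priors",
    "sample_weight",
    "agreement_index",
    "run_parameter_recovery",
    "run_distance_validation",
    "run_bias_study",
    "run_null_calibration",
]


@dataclass
class SimulationConfig:
    """Shared knobs of the three simulation studies.

    Weight components are uniform on (``k_low``, ``k_high``); priors come
    from :func:`sample_priors`; ``n_trials`` is the per-fit trial count and
    ``sigma`` the residual SD on the log-odds scale.
    """

    n_draws: int = 1000
    k_low: float = 0.1
    k_high: float = 1.5
    sigma: float = 1.0
    n_trials: int = 84
    seed: int = 0
    prior_mean_pct: float = 75.0
    prior_sd_pct: float = 15.0

    def __post_init__(self) -> None:
        if not self.k_low < self.k_high:
            raise ValueError("k_low must be < k_high")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.n_trials < 3:
            raise ValueError("n_trials must be >= 3")


@dataclass(frozen=True)
class BiasMap:
    """A linear reporting distortion in log-odds: reported = slope * latent.

    slope < 1 is underreporting (reports pulled toward no-preference),
    slope > 1 overreporting.  The zero intercept preserves the 50% point.
    """

    slope: float
    label: str

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def apply(self, C: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(C, dtype=float)


DEFAULT_BIAS_SETTINGS = (
    BiasMap(0.75, "mild_under"),
    BiasMap(0.5, "extreme_under"),
    BiasMap(4.0 / 3.0, "mild_over"),
    BiasMap(2.0, "extreme_over"),
)


def sample_priors(n_trials: int, rng: np.random.Generator, mean_pct: float = 75.0,
                  sd_pct: float = 15.0) -> np.ndarray:
    """Draw an (n_trials, 3) matrix of prior log-odds.

    A stand-in for the empirical prior distribution: the chosen option is
    uniform (sign +/-1) and the confidence percent follows a normal with the
    given mean and SD truncated to [50, 100], then capped at 99 before the
    log-odds transform.
    """
    a, b = (50.0 - mean_pct) / sd_pct, (100.0 - mean_pct) / sd_pct
    pct = truncnorm.rvs(a, b, loc=mean_pct, scale=sd_pct, size=(n_trials, 3), random_state=rng)
    pct = np.minimum(pct, 99.0)
    sign = np.where(rng.random((n_trials, 3)) < 0.5, -1.0, 1.0)
    return sign * logit(pct / 100.0)


def sample_weight(rng: np.random.Generator, k_low: float = 0.1, k_high: float = 1.5) -> np.ndarray:
    """One weight vector with independent uniform components."""
    return rng.uniform(k_low, k_high, size=3)


def _simulate_and_estimate(config: SimulationConfig, rng, k: np.ndarray, sigma: float,
                           n_trials: int, reported_transform=None):
    """One draw: priors, posteriors from truth, estimate from (possibly biased) reports."""
    X = sample_priors(n_trials, rng, config.prior_mean_pct, config.prior_sd_pct)
    y = X @ k + (rng.normal(0.0, sigma, size=n_trials) if sigma > 0 else 0.0)
    X_rep = X if reported_transform is None else reported_transform(X)
    k_hat, _, _, _ = solve_weights(X_rep, y)
    return X, y, k_hat


def run_parameter_recovery(config: SimulationConfig | None = None,
                           scales: tuple = (84, 252, 2520)) -> pd.DataFrame:
    """True-vs-estimated weight components at several trial-count scales.

    ``scales`` defaults to the study's design arithmetic: 84 trials per
    participant-condition, 252 per group (3 members), 2520 over the ten
    groups.

    Returns a tidy frame: draw, n_trials, component, true, estimated.
    """
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    rows = []
    for n_trials in scales:
        for d in range(config.n_draws):
            k = sample_weight(rng, config.k_low, config.k_high)
            _, _, k_hat = _simulate_and_estimate(config, rng, k, config.sigma, n_trials)
            for comp in range(3):
                rows.append({"draw": d, "n_trials": n_trials, "component": comp,
                             "true": k[comp], "estimated": k_hat[comp]})
    return pd.DataFrame(rows)


def agreement_index(posterior, flavor: str, prior=None, posterior2=None) -> float:
    """Sign-only agreement fraction validating a distance statistic.

    - ``self``: fraction of trials with sign(posterior) = sign(own prior);
      pass the member's prior log-odds as ``prior`` (1-D).
    - ``equality``: agreement with the equally-weighted sum; pass the full
      (n, 3) prior matrix as ``prior``.
    - ``similarity``: sign agreement between two posterior sets
      (``posterior`` and ``posterior2``) generated from two weight draws.

    A zero log-odds expresses no decision, so a zero sign on one side only
    counts as disagreement (both zero counts as agreement).
    """
    y1 = np.sign(np.asarray(posterior, dtype=float))
    if flavor == "self":
        if prior is None:
            raise ValueError("flavor 'self' needs the member's own prior")
        ref = np.sign(np.asarray(prior, dtype=float))
    elif flavor == "equality":
        if prior is None:
            raise ValueError("flavor 'equality' needs the (n, 3) prior matrix")
        ref = np.sign(np.asarray(prior, dtype=float).sum(axis=1))
    elif flavor == "similarity":
        if posterior2 is None:
            raise ValueError("flavor 'similarity' needs a second posterior set")
        ref = np.sign(np.asarray(posterior2, dtype=float))
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    return float(np.mean(y1 == ref))


def run_distance_validation(config: SimulationConfig | None = None,
                            sigmas: tuple = (1.0, 0.01)) -> pd.DataFrame:
    """Distance recovery plus agreement indices at each noise level.

    The self-weighting and equality metrics use one weight draw (attributed
    to member a); weight similarity and overall weight difference are both
    angles between two independent weight draws and are treated as one
    metric (``similarity``).

    Returns: metric, sigma, draw, true_distance, est_distance, agreement.
    """
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    axis_a = np.eye(3)[0]
    rows = []
    for sigma in sigmas:
        for d in range(config.n_draws):
            k1 = sample_weight(rng, config.k_low, config.k_high)
            k2 = sample_weight(rng, config.k_low, config.k_high)
            X, y1, k1_hat = _simulate_and_estimate(config, rng, k1, sigma, config.n_trials)
            noise2 = rng.normal(0.0, sigma, size=config.n_trials) if sigma > 0 else 0.0
            y2 = X @ k2 + noise2
            k2_hat, _, _, _ = solve_weights(X, y2)
            rows.append({"metric": "self_weighting", "sigma": sigma, "draw": d,
                         "true_distance": angular_distance(k1, axis_a),
                         "est_distance": angular_distance(k1_hat, axis_a),
                         "agreement": agreement_index(y1, "self", prior=X[:, 0])})
            rows.append({"metric": "weight_equality", "sigma": sigma, "draw": d,
                         "true_distance": angular_distance(k1, UNIFORM),
                         "est_distance": angular_distance(k1_hat, UNIFORM),
                         "agreement": agreement_index(y1, "equality", prior=X)})
            rows.append({"metric": "similarity", "sigma": sigma, "draw": d,
                         "true_distance": angular_distance(k1, k2),
                         "est_distance": angular_distance(k1_hat, k2_hat),
                         "agreement": agreement_index(y1, "similarity", posterior2=y2)})
    return pd.DataFrame(rows)


def run_bias_study(config: SimulationConfig | None = None,
                   bias_settings: tuple = DEFAULT_BIAS_SETTINGS,
                   biased_member: int = 1) -> pd.DataFrame:
    """Effect of one member's reporting bias on the distance estimates.

    Member ``biased_member`` (default b) reports ``slope * C`` while the
    posteriors are generated from the unbiased log-odds; sigma defaults to
    0.01 so that essentially all estimation error is bias-induced.
    Self-weighting is reported for member a — a *different* member than the
    biased one.  Each row pairs a true distance with its biased estimate and
    the estimate from the same draw without the bias transform (so slope = 1
    reproduces the unbiased column exactly).  Every setting reuses the same
    random substream, making settings directly comparable draw by draw.

    Returns: setting, slope, metric, draw, true_distance, est_distance,
    est_unbiased_distance.
    """
    if config is None:
        config = SimulationConfig(sigma=0.01)
    if not bias_settings:
        raise ValueError("bias_settings must be nonempty")
    axis_a = np.eye(3)[0]
    rows = []
    for bias in bias_settings:
        brng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

        def transform(X, _b=bias):
            Xr = X.copy()
            Xr[:, biased_member] = _b.apply(Xr[:, biased_member])
            return Xr

        for d in range(config.n_draws):
            k1 = sample_weight(brng, config.k_low, config.k_high)
            k2 = sample_weight(brng, config.k_low, config.k_high)
            X, y1, k1_hat = _simulate_and_estimate(config, brng, k1, config.sigma,
                                                   config.n_trials, reported_transform=transform)
            noise2 = brng.normal(0.0, config.sigma, size=config.n_trials)
            y2 = X @ k2 + noise2
            k2_hat, _, _, _ = solve_weights(transform(X), y2)
            k1_plain, _, _, _ = solve_weights(X, y1)
            k2_plain, _, _, _ = solve_weights(X, y2)
            for metric, true_d, est_d, plain_d in (
                ("self_weighting", angular_distance(k1, axis_a),
                 angular_distance(k1_hat, axis_a), angular_distance(k1_plain, axis_a)),
                ("weight_equality", angular_distance(k1, UNIFORM),
                 angular_distance(k1_hat, UNIFORM), angular_distance(k1_plain, UNIFORM)),
                ("similarity", angular_distance(k1, k2),
                 angular_distance(k1_hat, k2_hat), angular_distance(k1_plain, k2_plain)),
            ):
                rows.append({"setting": bias.label, "slope": bias.slope, "metric": metric,
                             "draw": d, "true_distance": true_d, "est_distance": est_d,
                             "est_unbiased_distance": plain_d})
    return pd.DataFrame(rows)


def run_null_calibration(n_replicates: int = 50, n_perm: int = 200, seed: int = 0,
                         sigma: float = 1.0) -> pd.DataFrame:
    """Type-I-error study: permutation p-values on no-effect synthetic triads.

    Each replicate generates one triad whose true weights are identical in
    both conditions, runs the participant-level permutation test for all
    four statistics, and records the p-values.  With trials exchangeable
    between conditions under this null, the empirical rejection rate at any
    alpha should match alpha (up to the mild discreteness of the add-one
    rule).

    Returns a tidy frame: replicate, statistic, member, p.
    """
    from .inference import STATISTICS, TAILS, permutation_p, permute_triad
    from .synthetic import (StudyDesign, generate_study, make_condition_effect,
                            sample_weight_table)

    rng = np.random.default_rng(seed)
    design = StudyDesign(n_groups=1)
    rows = []
    for rep in range(n_replicates):
        base = (sample_weight_table(design, rng).query("condition == 'quiet'")
                .drop(columns="condition").reset_index(drop=True))
        weights = make_condition_effect(base, effect="none")
        trials, _ = generate_study(design, weights=weights, sigma=sigma, rng=rng)
        observed, null, _ = permute_triad(trials, n_perm, rng)
        for s in STATISTICS:
            for i, member in enumerate(("a", "b", "c")):
                p = permutation_p(float(observed[s][i]), null[s][:, i], TAILS[s])
                rows.append({"replicate": rep, "statistic": s, "member": member, "p": p})
    return pd.DataFrame(rows)
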