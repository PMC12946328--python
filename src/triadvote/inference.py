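"""Permutation and bootstrap inference for the four weight statistics.

The condition contrast (noise vs. quiet) is tested without parametric
assumptions: condition labels are shuffled within each triad, weights are
re-estimated in the two pseudo-conditions, and the statistics recomputed,
yielding a permutation null per participant.  Whole trials are the
exchangeable unit (a trial carries the triad's three priors and three
posteriors, so the members' re-estimates stay aligned); shuffling whole
lists instead is available via ``unit="list"``.

Tail rules: overall weight change is nonnegative by construction, so its
test is one-tailed; the three noise-minus-quiet difference statistics are
two-tailed around zero.  p-values use the add-one rule
``(b + 1) / (m + 1)`` and never reach zero.

Population-level pooling is the median across participants (optionally with
an intermediate median within groups); its null distribution pools the
aligned permutation draws the same way.  Error bars are percentile
bootstrap intervals: participants are resampled at the population level,
and trials within participants at the group level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision import MEMBERS
from .estimation import PRIOR_COLS, POST_COLS, solve_weights
from .geometry import PAIRS, angular_distance, self_weighting, weight_equality

__all__ = [
    "STATISTICS",
    "TestResult",
    "PermutationOutcome",
    "triad_statistics",
    "permute_triad",
    "run_permutation_tests",
    "participant_results",
    "group_results",
    "population_results",
    "pool",
    "population_null",
    "permutation_p",
    "bootstrap_ci",
    "bootstrap_group_ci",
    "sensitivity_rerun",
    "full_analysis",
]

#: The four condition-contrast statistics, per participant.
STATISTICS = ("overall_change", "self_weighting", "weight_equality", "weight_similarity")

#: Tail rule per statistic: overall change is nonnegative, hence one-tailed.
TAILS = {
    "overall_change": "one",
    "self_weighting": "two",
    "weight_equality": "two",
    "weight_similarity": "two",
}


@dataclass
class TestResult:
    """A tested statistic: observed value, permutation p, bootstrap CI."""

    statistic: str
    level: str
    subject: str
    observed: float
    p_value: float
    n_permutations: int
    tails: str
    ci: tuple | None = None
    n_bootstrap: int = 0
    null_samples: np.ndarray | None = field(default=None, repr=False)
    n_failed: int = 0


def _pair_values(K: np.ndarray) -> dict:
    return {(i, j): angular_distance(K[MEMBERS.index(i)], K[MEMBERS.index(j)]) for i, j in PAIRS}


def _member_similarity(pairs: dict, pair_mode: str) -> np.ndarray:
    """Per-member similarity value: mean of the pair angles involving the member."""
    if pair_mode not in ("both", "mean"):
        raise ValueError("pair_mode must be 'both' or 'mean'")
    vals = np.zeros(3)
    for m_idx, m in enumerate(MEMBERS):
        angles = [v for (i, j), v in pairs.items() if m in (i, j)]
        vals[m_idx] = float(np.mean(angles))
    return vals


def triad_statistics(k_noise: np.ndarray, k_quiet: np.ndarray, pair_mode: str = "both") -> dict:
    """The four statistics for one triad, per member (a, b, c order).

    ``k_noise`` and ``k_quiet`` are (3, 3) arrays of weight vectors, rows in
    member order.  ``overall_change`` is the (nonnegative) angle between the
    two conditions' weights; the other three are noise-minus-quiet
    differences of the within-condition statistic.
    """
    out = {}
    out["overall_change"] = np.array(
        [angular_distance(k_noise[i], k_quiet[i]) for i in range(3)]
    )
    out["self_weighting"] = np.array(
        [self_weighting(k_noise[i], MEMBERS[i]) - self_weighting(k_quiet[i], MEMBERS[i])
         for i in range(3)]
    )
    out["weight_equality"] = np.array(
        [weight_equality(k_noise[i]) - weight_equality(k_quiet[i]) for i in range(3)]
    )
    pn, pq = _pair_values(k_noise), _pair_values(k_quiet)
    out["weight_similarity"] = _member_similarity(pn, pair_mode) - _member_similarity(pq, pair_mode)
    return out


def _fit_split(X, Y, idx_noise, idx_quiet):
    """Fit both pseudo-conditions; returns (K_noise, K_quiet, ok)."""
    kN, _, _, convN = solve_weights(X[idx_noise], Y[idx_noise])
    kQ, _, _, convQ = solve_weights(X[idx_quiet], Y[idx_quiet])
    return kN.T, kQ.T, (convN and convQ)  # rows = members


def permute_triad(triad: pd.DataFrame, n_perm: int, rng: np.random.Generator,
                  unit: str = "trial", pair_mode: str = "both",
                  conditions: tuple = ("noise", "quiet")):
    """Observed statistics and their permutation null for one triad.

    Returns ``(observed, null, n_failed)`` where ``observed`` maps each
    statistic to a length-3 per-member array and ``null`` to an
    ``(n_perm, 3)`` array (rows with a degenerate re-estimate are NaN and
    counted in ``n_failed``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if unit not in ("trial", "list"):
        raise ValueError("unit must be 'trial' or 'list'")
    cond = triad["condition"].to_numpy()
    present = set(cond)
    if set(conditions) - present:
        raise ValueError(f"triad lacks conditions {set(conditions) - present}")
    X = triad[PRIOR_COLS].to_numpy(dtype=float)
    Y = triad[POST_COLS].to_numpy(dtype=float)
    is_noise = cond == conditions[0]
    idx_n, idx_q = np.flatnonzero(is_noise), np.flatnonzero(~is_noise)
    kN, kQ, ok = _fit_split(X, Y, idx_n, idx_q)
    if not ok:
        raise ValueError("observed data give a degenerate weight system")
    observed = triad_statistics(kN, kQ, pair_mode)

    n = len(triad)
    n_noise = int(is_noise.sum())
    if unit == "list":
        lists = triad["list"].to_numpy()
        unique_lists = pd.unique(lists)
        noise_lists = {l for l in unique_lists if (cond[lists == l] == conditions[0]).all()}
        n_noise_lists = len(noise_lists)
    null = {s: np.full((n_perm, 3), np.nan) for s in STATISTICS}
    n_failed = 0
    for m in range(n_perm):
        if unit == "trial":
            perm = rng.permutation(n)
            pidx_n, pidx_q = perm[:n_noise], perm[n_noise:]
        else:
            lperm = rng.permutation(unique_lists)
            chosen = set(lperm[:n_noise_lists])
            mask = np.isin(lists, list(chosen))
            pidx_n, pidx_q = np.flatnonzero(mask), np.flatnonzero(~mask)
        try:
            pkN, pkQ, ok = _fit_split(X, Y, pidx_n, pidx_q)
        except Exception:
            ok = False
        if not ok:
            n_failed += 1
            continue
        stats = triad_statistics(pkN, pkQ, pair_mode)
        for s in STATISTICS:
            null[s][m] = stats[s]
    return observed, null, n_failed


@dataclass
class PermutationOutcome:
    """All triads' observed statistics and aligned permutation nulls.

    ``null[statistic]`` is an ``(n_perm, n_participants)`` matrix whose draw
    m combines every triad's m-th (independent) shuffle, so pooled null
    statistics can be formed draw-wise.
    """

    observed: pd.DataFrame           # columns: group, member, statistic, value
    null: dict                       # statistic -> (n_perm, n_participants)
    participants: pd.DataFrame       # columns: group, member (column order of null)
    n_perm: int
    n_failed: dict                   # group -> count of failed permutations
    unit: str
    pair_mode: str


def run_permutation_tests(trials: pd.DataFrame, n_perm: int = 10000,
                          rng: np.random.Generator | None = None, unit: str = "trial",
                          pair_mode: str = "both",
                          conditions: tuple = ("noise", "quiet")) -> PermutationOutcome:
    """Permutation machinery for a whole dataset, one shuffle stream per triad."""
    rng = np.random.default_rng() if rng is None else rng
    obs_rows, part_rows, null_cols = [], [], {s: [] for s in STATISTICS}
    n_failed = {}
    for group, triad in trials.groupby("group", sort=True):
        observed, null, failed = permute_triad(
            triad, n_perm, rng, unit=unit, pair_mode=pair_mode, conditions=conditions)
        n_failed[group] = failed
        for m_idx, member in enumerate(MEMBERS):
            part_rows.append({"group": group, "member": member})
            for s in STATISTICS:
                obs_rows.append({"group": group, "member": member,
                                 "statistic": s, "value": observed[s][m_idx]})
            for s in STATISTICS:
                null_cols[s].append(null[s][:, m_idx])
    return PermutationOutcome(
        observed=pd.DataFrame(obs_rows),
        null={s: np.column_stack(null_cols[s]) for s in STATISTICS},
        participants=pd.DataFrame(part_rows),
        n_perm=n_perm, n_failed=n_failed, unit=unit, pair_mode=pair_mode,
    )


def permutation_p(observed: float, null: np.ndarray, tails: str) -> float:
    """Add-one permutation p-value; NaN draws (failed re-estimates) excluded."""
    null = np.asarray(null, dtype=float)
    null = null[~np.isnan(null)]
    m = null.size
    if m == 0:
        return np.nan
    if tails == "one":
        b = int(np.sum(null >= observed))
    elif tails == "two":
        b = int(np.sum(np.abs(null) >= np.abs(observed)))
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return (b + 1) / (m + 1)


def pool(values, intermediate: bool = False, groups=None) -> float:
    """Median pooling across participants, optionally via group medians first."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot pool an empty set of values")
    if not intermediate:
        return float(np.nanmedian(values))
    if groups is None:
        raise ValueError("intermediate pooling requires group labels")
    groups = np.asarray(groups)
    medians = [np.nanmedian(values[groups == g]) for g in pd.unique(groups)]
    return float(np.nanmedian(medians))


def population_null(observed_values, null_matrix, statistic: str, groups=None,
                    intermediate: bool = False):
    """Pooled observed value, its draw-wise pooled null, and the p-value."""
    obs = pool(observed_values, intermediate=intermediate, groups=groups)
    null_matrix = np.asarray(null_matrix, dtype=float)
    if null_matrix.shape[1] != len(np.asarray(observed_values)):
        raise ValueError("null draws are misaligned with the participant values")
    if intermediate:
        groups = np.asarray(groups)
        ug = pd.unique(groups)
        group_meds = np.column_stack(
            [np.nanmedian(null_matrix[:, groups == g], axis=1) for g in ug])
        null_pooled = np.nanmedian(group_meds, axis=1)
    else:
        null_pooled = np.nanmedian(null_matrix, axis=1)
    p = permutation_p(obs, null_pooled, TAILS[statistic])
    return obs, null_pooled, p


def bootstrap_ci(values, n_boot: int = 10000, rng: np.random.Generator | None = None,
                 intermediate: bool = False, groups=None) -> tuple:
    """Percentile 95% CI of the pooled median, resampling participants."""
    import warnings

    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile intervals", stacklevel=2)
    rng = np.random.default_rng() if rng is None else rng
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    groups = None if groups is None else np.asarray(groups)
    n = values.size
    meds = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        meds[b] = pool(values[idx], intermediate=intermediate,
                       groups=None if groups is None else groups[idx])
    return (float(np.percentile(meds, 2.5)), float(np.percentile(meds, 97.5)))


def bootstrap_group_ci(triad: pd.DataFrame, statistic: str, n_boot: int = 1000,
                       rng: np.random.Generator | None = None, pair_mode: str = "both",
                       conditions: tuple = ("noise", "quiet")) -> tuple:
    """Group-level percentile CI by resampling trials within each condition.

    Three members are too few to resample, so the uncertainty of a group's
    median statistic is propagated from the trial level: trials are drawn
    with replacement within each condition, weights refitted, and the median
    of the three members' statistic recomputed.
    """
    rng = np.random.default_rng() if rng is None else rng
    X = triad[PRIOR_COLS].to_numpy(dtype=float)
    Y = triad[POST_COLS].to_numpy(dtype=float)
    is_noise = triad["condition"].to_numpy() == conditions[0]
    idx_n, idx_q = np.flatnonzero(is_noise), np.flatnonzero(~is_noise)
    meds = np.full(n_boot, np.nan)
    for b in range(n_boot):
        rn = rng.choice(idx_n, size=idx_n.size, replace=True)
        rq = rng.choice(idx_q, size=idx_q.size, replace=True)
        try:
            kN, kQ, ok = _fit_split(X, Y, rn, rq)
        except Exception:
            continue
        if ok:
            meds[b] = np.median(triad_statistics(kN, kQ, pair_mode)[statistic])
    meds = meds[~np.isnan(meds)]
    return (float(np.percentile(meds, 2.5)), float(np.percentile(meds, 97.5)))


def participant_results(outcome: PermutationOutcome) -> pd.DataFrame:
    """Per-participant p-values for all four statistics."""
    rows = []
    obs = outcome.observed.set_index(["group", "member", "statistic"])["value"]
    for col, (_, part) in enumerate(outcome.participants.iterrows()):
        g, m = part["group"], part["member"]
        for s in STATISTICS:
            o = float(obs.loc[(g, m, s)])
            rows.append({
                "statistic": s, "level": "participant", "subject": f"{g}-{m}",
                "group": g, "member": m, "observed": o,
                "p": permutation_p(o, outcome.null[s][:, col], TAILS[s]),
                "n_perm": outcome.n_perm, "tails": TAILS[s],
                "n_failed": outcome.n_failed[g],
            })
    return pd.DataFrame(rows)


def group_results(outcome: PermutationOutcome) -> pd.DataFrame:
    """Group statistic = median of the three members, against its aligned null."""
    rows = []
    parts = outcome.participants
    for g in pd.unique(parts["group"]):
        cols = np.flatnonzero((parts["group"] == g).to_numpy())
        for s in STATISTICS:
            obs_vals = outcome.observed.query("group == @g and statistic == @s")["value"]
            o = float(np.median(obs_vals))
            null_med = np.nanmedian(outcome.null[s][:, cols], axis=1)
            rows.append({
                "statistic": s, "level": "group", "subject": str(g), "group": g,
                "observed": o, "p": permutation_p(o, null_med, TAILS[s]),
                "n_perm": outcome.n_perm, "tails": TAILS[s],
                "n_failed": outcome.n_failed[g],
            })
    return pd.DataFrame(rows)


def population_results(outcome: PermutationOutcome, n_boot: int = 10000,
                       rng: np.random.Generator | None = None,
                       intermediate: bool = False,
                       excluded_groups: set | None = None) -> pd.DataFrame:
    """Population-level pooled medians with permutation p and bootstrap CI."""
    rng = np.random.default_rng() if rng is None else rng
    excluded = set() if excluded_groups is None else set(excluded_groups)
    parts = outcome.participants
    keep = ~parts["group"].isin(excluded).to_numpy()
    if not keep.any():
        raise ValueError("excluding all groups leaves nothing to pool")
    groups = parts["group"].to_numpy()[keep]
    rows = []
    for s in STATISTICS:
        obs_s = (outcome.observed.query("statistic == @s")
                 .set_index(["group", "member"])["value"])
        vals = np.array([obs_s.loc[(g, m)] for g, m in
                         parts.loc[keep, ["group", "member"]].itertuples(index=False)])
        null_mat = outcome.null[s][:, keep]
        o, null_pooled, p = population_null(vals, null_mat, s, groups=groups,
                                            intermediate=intermediate)
        lo, hi = bootstrap_ci(vals, n_boot=n_boot, rng=rng,
                              intermediate=intermediate, groups=groups)
        rows.append({
            "statistic": s, "level": "population", "subject": "all",
            "observed": o, "p": p, "ci_low": lo, "ci_high": hi,
            "n_perm": outcome.n_perm, "n_boot": n_boot, "tails": TAILS[s],
            "intermediate_pooling": intermediate,
            "excluded_groups": ",".join(sorted(map(str, excluded))) or "",
            "n_participants": int(keep.sum()),
        })
    return pd.DataFrame(rows)


def sensitivity_rerun(outcome: PermutationOutcome, excluded_groups: set,
                      n_boot: int = 10000, rng: np.random.Generator | None = None,
                      intermediate: bool = False) -> pd.DataFrame:
    """Population results with the given groups omitted (outlier check)."""
    bad = set(excluded_groups) - set(outcome.participants["group"])
    if bad:
        raise ValueError(f"unknown groups in exclusion set: {sorted(bad)}")
    return population_results(outcome, n_boot=n_boot, rng=rng,
                              intermediate=intermediate, excluded_groups=excluded_groups)


def full_analysis(trials: pd.DataFrame, n_perm: int = 10000, n_boot: int = 10000,
                  rng: np.random.Generator | None = None, unit: str = "trial",
                  pair_mode: str = "both", excluded_groups: set | None = None,
                  conditions: tuple = ("noise", "quiet")) -> dict:
    """The complete inferential pipeline on one dataset.

    Returns a dict of DataFrames: ``participant``, ``group``, ``population``
    (plain and with intermediate pooling), and — when ``excluded_groups`` is
    given — a ``sensitivity`` rerun without those groups.
    """
    rng = np.random.default_rng() if rng is None else rng
    outcome = run_permutation_tests(trials, n_perm=n_perm, rng=rng, unit=unit,
                                    pair_mode=pair_mode, conditions=conditions)
    tables = {
        "participant": participant_results(outcome),
        "group": group_results(outcome),
        "population": population_results(outcome, n_boot=n_boot, rng=rng),
        "population_intermediate": population_results(outcome, n_boot=n_boot, rng=rng,
                                                      intermediate=True),
    }
    if excluded_groups:
        tables["sensitivity"] = sensitivity_rerun(outcome, excluded_groups,
                                                  n_boot=n_boot, rng=rng)
    return tables
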