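"""Synthetic triadic decision experiments with the study's full design.

Emulates the behavioural study this package analyzes: ten triads, two
communication conditions (noise / quiet), three question lists per
condition, and 28 binary trials per list (all unordered pairs of 8 items;
lists are disjoint across conditions so no item repeats).  Prior
confidences are drawn from the simulation prior distribution; posteriors
follow the generative weighted-voting model with known per-member,
per-condition weight vectors, which are emitted alongside the trials so
recovery can be checked end to end.

Item topics (movies, landmarks, countries) are synthetic labels only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .confidence import decode_percent
from .decision import MEMBERS
from .validation import sample_priors, sample_weight

__all__ = [
    "StudyDesign",
    "generate_study",
    "sample_weight_table",
    "make_condition_effect",
    "emit_percent_scale",
    "WIDE_COLUMNS",
]

#: Canonical wide-format trial schema (one row per trial).
WIDE_COLUMNS = ["group", "condition", "topic", "list", "trial",
                "item_1", "item_2", "C_a", "C_b", "C_c", "Cp_a", "Cp_b", "Cp_c"]

DEFAULT_TOPICS = ("movies", "landmarks", "countries")


@dataclass
class StudyDesign:
    """The experiment's factorial layout."""

    n_groups: int = 10
    members_per_group: int = 3
    conditions: tuple = ("noise", "quiet")
    lists_per_condition: int = 3
    items_per_list: int = 8

    def __post_init__(self) -> None:
        if self.members_per_group != 3:
            raise ValueError("the model is defined for triads (members_per_group = 3)")
        if self.n_groups < 1 or self.lists_per_condition < 1 or self.items_per_list < 2:
            raise ValueError("invalid design arithmetic")

    @property
    def trials_per_list(self) -> int:
        """All unordered item pairs: m(m-1)/2."""
        return self.items_per_list * (self.items_per_list - 1) // 2

    @property
    def trials_per_condition(self) -> int:
        return self.trials_per_list * self.lists_per_condition

    @property
    def n_trials(self) -> int:
        return self.trials_per_condition * len(self.conditions) * self.n_groups


def sample_weight_table(design: StudyDesign, rng: np.random.Generator,
                        k_low: float = 0.1, k_high: float = 1.5) -> pd.DataFrame:
    """Independent true weights per (group, condition, member)."""
    rows = []
    for g in range(design.n_groups):
        group = chr(ord("A") + g) if g < 26 else f"G{g}"
        for condition in design.conditions:
            for member in MEMBERS:
                k = sample_weight(rng, k_low, k_high)
                rows.append({"group": group, "condition": condition, "member": member,
                             "k_a": k[0], "k_b": k[1], "k_c": k[2]})
    return pd.DataFrame(rows)


def _rotate_toward_random(k: np.ndarray, angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate k by exactly `angle` within the plane of k and a random orthogonal direction."""
    norm = np.linalg.norm(k)
    khat = k / norm
    v = rng.standard_normal(3)
    w = v - (v @ khat) * khat
    wn = np.linalg.norm(w)
    while wn < 1e-12:  # essentially never: resample a degenerate direction
        v = rng.standard_normal(3)
        w = v - (v @ khat) * khat
        wn = np.linalg.norm(w)
    what = w / wn
    return norm * (np.cos(angle) * khat + np.sin(angle) * what)


def make_condition_effect(base_weights: pd.DataFrame, effect: str = "none",
                          magnitude: float = 0.0,
                          rng: np.random.Generator | None = None,
                          conditions: tuple = ("noise", "quiet")) -> pd.DataFrame:
    """Derive a two-condition weight table with a known ground-truth effect.

    ``base_weights`` holds one row per (group, member) with columns
    k_a, k_b, k_c; these become the quiet-condition weights.  Effects:

    - ``none``: identical weights in both conditions (null scenario);
    - ``rotate_by_angle``: noise weights rotated so the overall weight
      change equals ``magnitude`` radians exactly;
    - ``self_shift``: noise weights shifted toward each member's own axis
      by ``magnitude`` times the vector norm, so self-weighting distance is
      strictly smaller in noise.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be nonnegative")
    if effect == "rotate_by_angle" and magnitude > np.pi:
        raise ValueError("rotation angle cannot exceed pi")
    if effect not in ("none", "rotate_by_angle", "self_shift"):
        raise ValueError(f"unknown effect {effect!r}")
    rng = np.random.default_rng() if rng is None else rng
    noise_cond, quiet_cond = conditions
    rows = []
    for _, r in base_weights.iterrows():
        k = np.array([r["k_a"], r["k_b"], r["k_c"]], dtype=float)
        if effect == "none" or magnitude == 0:
            k_noise = k
        elif effect == "rotate_by_angle":
            k_noise = _rotate_toward_random(k, magnitude, rng)
        else:
            axis = np.eye(3)[MEMBERS.index(r["member"])]
            k_noise = k + magnitude * np.linalg.norm(k) * axis
        for condition, kk in ((quiet_cond, k), (noise_cond, k_noise)):
            rows.append({"group": r["group"], "condition": condition, "member": r["member"],
                         "k_a": kk[0], "k_b": kk[1], "k_c": kk[2]})
    return pd.DataFrame(rows)


def generate_study(design: StudyDesign | None = None,
                   weights: pd.DataFrame | None = None,
                   sigma: float = 1.0, seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   prior_mean_pct: float = 75.0, prior_sd_pct: float = 15.0,
                   clip_posteriors: bool = False):
    """Generate a complete synthetic experiment.

    Parameters
    ----------
    weights : DataFrame, optional
        True weights per (group, condition, member); sampled uniformly on
        (0.1, 1.5) per component when omitted.
    sigma : float
        Residual SD of posterior log-odds.
    clip_posteriors : bool
        Clip simulated posterior log-odds to the +/- ln(99) reporting range
        (off by default: simulations keep the unclipped model draws).

    Returns
    -------
    (trials, weights) : wide-format trial DataFrame (``WIDE_COLUMNS``) and
    the true weight table actually used.
    """
    design = StudyDesign() if design is None else design
    if rng is None:
        rng = np.random.default_rng(seed)
    if weights is None:
        weights = sample_weight_table(design, rng)
    widx = weights.set_index(["group", "condition", "member"])
    topics = (DEFAULT_TOPICS if design.lists_per_condition == len(DEFAULT_TOPICS)
              else tuple(f"topic{t + 1}" for t in range(design.lists_per_condition)))
    groups = pd.unique(weights["group"])
    rows = []
    from .confidence import LOG_ODDS_BOUND

    for group in groups:
        for condition in design.conditions:
            K = np.column_stack([
                widx.loc[(group, condition, m), ["k_a", "k_b", "k_c"]].to_numpy(dtype=float)
                for m in MEMBERS])  # (3 source, 3 member)
            for li, topic in enumerate(topics):
                # disjoint item pools: condition-specific list labels
                list_id = f"{topic}-{condition}"
                items = [f"{topic}-{condition}-item{i + 1}" for i in range(design.items_per_list)]
                pairs = list(combinations(items, 2))
                priors = sample_priors(len(pairs), rng, prior_mean_pct, prior_sd_pct)
                post = priors @ K
                if sigma > 0:
                    post = post + rng.normal(0.0, sigma, size=post.shape)
                if clip_posteriors:
                    post = np.clip(post, -LOG_ODDS_BOUND, LOG_ODDS_BOUND)
                for t, (i1, i2) in enumerate(pairs):
                    rows.append({
                        "group": group, "condition": condition, "topic": topic,
                        "list": list_id, "trial": t + 1, "item_1": i1, "item_2": i2,
                        "C_a": priors[t, 0], "C_b": priors[t, 1], "C_c": priors[t, 2],
                        "Cp_a": post[t, 0], "Cp_b": post[t, 1], "Cp_c": post[t, 2],
                    })
    return pd.DataFrame(rows, columns=WIDE_COLUMNS), weights


def emit_percent_scale(trials: pd.DataFrame, rounded: bool = True) -> pd.DataFrame:
    """Render a wide log-odds trial table as percent-scale reports.

    One row per (trial x member x phase) with choice and confidence_pct on
    the interface's 50-99% scale — the schema a reader of the deposited raw
    data maps onto.  Option 1 of each trial is the canonical direction.
    """
    rows = []
    key_cols = ["group", "condition", "topic", "list", "trial", "item_1", "item_2"]
    for _, r in trials.iterrows():
        for member in MEMBERS:
            for phase, col in (("prior", f"C_{member}"), ("posterior", f"Cp_{member}")):
                choice, pct = decode_percent(r[col], rounded=rounded)
                row = {c: r[c] for c in key_cols if c in trials.columns}
                row.update(member=member, phase=phase,
                           choice=str(choice[0]), confidence_pct=float(pct[0]))
                rows.append(row)
    return pd.DataFrame(rows)
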