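"""Model/Results interface over the weighted-voting pipeline.

``GroupDecisionModel`` wraps a trial dataset (wide log-odds table, long
percent-scale table, or CSV file); ``fit()`` solves the closed-form
maximum-likelihood weight systems and returns a ``GroupDecisionResults``
carrying the weight table, the angular summary statistics, and methods for
permutation/bootstrap inference, sensitivity reruns, ternary export and
model-based resimulation.

    >>> model = GroupDecisionModel.from_csv("trials.csv")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> tables = res.permutation_test(n_permutations=10000, seed=7)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decision import MEMBERS
from .estimation import (PRIOR_COLS, POST_COLS, fit_dataset, flag_negative_weights,
                         weights_as_matrix)
from .geometry import (angular_distance, self_weighting, ternary_coordinates,
                       weight_equality, weight_similarity)
from . import inference
from .io import read_trials, long_to_wide

__all__ = ["GroupDecisionModel", "GroupDecisionResults"]


class GroupDecisionModel:
    """A confidence-weighted voting model of triadic decisions.

    Parameters
    ----------
    trials : DataFrame
        Wide trial table with columns ``group, condition, list, trial,
        C_a..C_c, Cp_a..Cp_c`` (log-odds).  Use :meth:`from_long` or
        :meth:`from_csv` for percent-scale input.
    conditions : tuple
        The two condition labels, noise-like first (sign convention of the
        difference statistics).
    """

    def __init__(self, trials: pd.DataFrame, conditions: tuple = ("noise", "quiet")):
        needed = {"group", "condition"} | set(PRIOR_COLS) | set(POST_COLS)
        missing = needed - set(trials.columns)
        if missing:
            raise ValueError(f"trial table lacks columns {sorted(missing)}")
        self.trials = trials.reset_index(drop=True)
        self.conditions = conditions

    @classmethod
    def from_long(cls, long_df: pd.DataFrame, conditions: tuple = ("noise", "quiet")):
        """Build from a long percent-scale report table."""
        return cls(long_to_wide(long_df), conditions=conditions)

    @classmethod
    def from_csv(cls, path, schema: dict | None = None,
                 conditions: tuple = ("noise", "quiet")):
        """Build from a long-format CSV, optionally schema-mapped."""
        return cls(read_trials(path, schema=schema), conditions=conditions)

    def fit(self, by_list: bool = False) -> "GroupDecisionResults":
        """Closed-form ML fit of every (group, member, condition) weight vector."""
        weights = fit_dataset(self.trials, by_list=by_list)
        return GroupDecisionResults(self, weights, by_list=by_list)

    def simulate(self, weights: pd.DataFrame, sigma: float,
                 rng: np.random.Generator) -> pd.DataFrame:
        """Resimulate posteriors at the observed priors from given weights."""
        out = self.trials.copy()
        for (group, condition), sub in out.groupby(["group", "condition"]):
            K = weights_as_matrix(weights, group, condition).T  # (source, member)
            means = sub[PRIOR_COLS].to_numpy(dtype=float) @ K
            noise = rng.normal(0.0, sigma, size=means.shape) if sigma > 0 else 0.0
            out.loc[sub.index, POST_COLS] = means + noise
        return out


class GroupDecisionResults:
    """Fitted weights plus everything derived from them."""

    def __init__(self, model: GroupDecisionModel, weights: pd.DataFrame, by_list: bool = False):
        self.model = model
        self.weights = weights
        self.by_list = by_list

    # ------------------------------------------------------------------ #
    def flag_negative_weights(self, threshold: float = 0.0, large: float = -0.1) -> pd.DataFrame:
        """Negative-component flags; large negatives nominate outlier groups."""
        return flag_negative_weights(self.weights, threshold=threshold, large=large)

    def outlier_groups(self, large: float = -0.1) -> set:
        """Groups holding at least one large-negative weight component."""
        flags = self.flag_negative_weights(large=large)
        return set(flags.loc[flags["large_negative"], "group"])

    # ------------------------------------------------------------------ #
    def distance_statistics(self) -> pd.DataFrame:
        """Tidy table of the four angular statistics at participant level.

        Within-condition statistics (self-weighting, equality, similarity)
        appear once per condition plus as a noise-minus-quiet difference;
        overall change is the single cross-condition angle.
        """
        noise_c, quiet_c = self.model.conditions
        rows = []
        for group in pd.unique(self.weights["group"]):
            kN = weights_as_matrix(self.weights, group, noise_c)
            kQ = weights_as_matrix(self.weights, group, quiet_c)
            per_cond = {noise_c: kN, quiet_c: kQ}
            for i, member in enumerate(MEMBERS):
                rows.append({"level": "participant", "group": group, "member": member,
                             "statistic": "overall_change", "condition": "noise-vs-quiet",
                             "value_rad": angular_distance(kN[i], kQ[i])})
                for cond, K in per_cond.items():
                    rows.append({"level": "participant", "group": group, "member": member,
                                 "statistic": "self_weighting", "condition": cond,
                                 "value_rad": self_weighting(K[i], member)})
                    rows.append({"level": "participant", "group": group, "member": member,
                                 "statistic": "weight_equality", "condition": cond,
                                 "value_rad": weight_equality(K[i])})
            for cond, K in per_cond.items():
                for (i, j), v in weight_similarity(K).items():
                    rows.append({"level": "pair", "group": group, "member": f"{i}-{j}",
                                 "statistic": "weight_similarity", "condition": cond,
                                 "value_rad": v})
        return pd.DataFrame(rows)

    def condition_differences(self, pair_mode: str = "both") -> pd.DataFrame:
        """Per-participant values of the four condition-contrast statistics."""
        noise_c, quiet_c = self.model.conditions
        rows = []
        for group in pd.unique(self.weights["group"]):
            kN = weights_as_matrix(self.weights, group, noise_c)
            kQ = weights_as_matrix(self.weights, group, quiet_c)
            stats = inference.triad_statistics(kN, kQ, pair_mode=pair_mode)
            for s, vals in stats.items():
                for i, member in enumerate(MEMBERS):
                    rows.append({"group": group, "member": member,
                                 "statistic": s, "value_rad": float(vals[i])})
        return pd.DataFrame(rows)

    def ternary_coordinates(self) -> pd.DataFrame:
        """Simplex-projected weights for ternary plotting, with bound flags."""
        rows = []
        for _, r in self.weights.iterrows():
            xy, out = ternary_coordinates(np.array([r["k_a"], r["k_b"], r["k_c"]]))
            rows.append({"group": r["group"], "member": r["member"],
                         "condition": r["condition"], "x": xy[0], "y": xy[1],
                         "out_of_bounds": out})
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------ #
    def permutation_test(self, n_permutations: int = 10000, n_bootstrap: int = 10000,
                         seed: int | None = None, unit: str = "trial",
                         pair_mode: str = "both",
                         excluded_groups: set | None = None) -> dict:
        """Full permutation/bootstrap inference; see :func:`inference.full_analysis`."""
        rng = np.random.default_rng(seed)
        return inference.full_analysis(
            self.model.trials, n_perm=n_permutations, n_boot=n_bootstrap, rng=rng,
            unit=unit, pair_mode=pair_mode, excluded_groups=excluded_groups,
            conditions=self.model.conditions)

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        """Readable overview: fit dimensions, sigma, and pooled statistics."""
        w = self.weights
        noise_c, quiet_c = self.model.conditions
        diffs = self.condition_differences()
        lines = []
        lines.append("Confidence-weighted voting model — fitted weights")
        lines.append("=" * 58)
        lines.append(f"Groups: {w['group'].nunique():>3}    participants: "
                     f"{len(w.groupby(['group', 'member'])):>3}    "
                     f"weight vectors: {len(w):>4}")
        lines.append(f"Conditions: {noise_c}, {quiet_c}    "
                     f"trials per fit (median): {int(w['n_trials'].median())}")
        lines.append(f"Residual SD sigma (median [min, max]): "
                     f"{w['sigma'].median():.3f} [{w['sigma'].min():.3f}, "
                     f"{w['sigma'].max():.3f}]")
        n_neg = int((w[["k_a", "k_b", "k_c"]].min(axis=1) < 0).sum())
        lines.append(f"Weight vectors with a negative component: {n_neg}")
        if not w["converged"].all():
            lines.append(f"WARNING: {int((~w['converged']).sum())} degenerate fits "
                         "(min-norm solutions)")
        lines.append("-" * 58)
        lines.append("Population medians (noise-minus-quiet where applicable):")
        for s in inference.STATISTICS:
            vals = diffs.loc[diffs["statistic"] == s, "value_rad"]
            lines.append(f"  {s:<18} {vals.median():+.4f} rad")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<GroupDecisionResults: {self.weights['group'].nunique()} groups, "
                f"{len(self.weights)} weight vectors>")
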