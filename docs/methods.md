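# Methods

This note documents the statistical model behind `triadvote`, the choices
made where the design was genuinely open, the numerical conventions, and
what the synthetic-data studies do and do not demonstrate.

## The decision model

A triad answers binary questions twice: individually before a group
discussion (prior) and individually after it (posterior). Each answer is a
choice plus a confidence percent in [50, 100], encoded as a signed
probability toward a canonical option and transformed to log-odds
`C = ln(c/(1−c))`. Within a trial, option 1 of the question is the
canonical positive direction for all members; any fixed per-trial
convention gives identical weight estimates because the model is
sign-equivariant.

Member *j*'s posterior log-odds is modelled as

    C_j^p ~ N( k_{j,a} C_a + k_{j,b} C_b + k_{j,c} C_c , σ ),

a linear Gaussian model without intercept: a triad with three indifferent
priors is forced to an indifferent expected posterior. σ is a standard
deviation on the log-odds scale, shared across members and trials, and
each member's noise is drawn independently within a trial — the model does
not represent cross-member error correlation, agreement-dependent
weighting, or transitive inference across related questions.

### Truncation

100% ratings are truncated to 99% before the log-odds transform so |C|
never exceeds ln(99) ≈ 4.5951. The truncation is implemented as a hard cap
`min(pct, 99)`: for whole-percent ratings this is exactly the 100 → 99
rule, and it extends the bound to fractional ratings from a continuous
slider, keeping the log-odds magnitude bounded for every valid report (the
reason the rule exists). No truncation is needed at the low end; the scale
bottoms out at 50% (C = 0).

## Weight estimation

The Gaussian log-likelihood in `k_j` is a least-squares criterion, so the
MLE solves the 3×3 normal equations `(Σ C_n C_nᵀ) k_j = Σ C_n C^p_{j,n}`.
All members of a triad share the prior matrix within a condition, so one
Gram factorization serves the three members. Conventions:

- **σ estimator**: σ̂ = √(RSS/N), the MLE under the same likelihood (no
  degrees-of-freedom correction). On synthetic data generated at σ = 1
  with N = 84, fitted σ̂ concentrate near 1 (see the worked example).
- **Degenerate systems**: when the Gram matrix condition number exceeds
  1e10 (priors essentially confined to a line or plane), the minimum-norm
  least-squares solution is returned and flagged `converged=False` rather
  than raising, so permutation resamples never abort; the condition number
  is always recorded. With continuous confidence data this essentially
  never occurs (it requires an exactly rank-deficient design).
- **No sign constraint**: weights may be negative (a member deliberately
  going against another's judgement); vectors with components below −0.1
  are flagged as "large negative" to nominate potential outlier groups for
  sensitivity reruns, mirroring how such anomalies are handled in
  practice. The −0.1 default separates visible anomalies from near-zero
  statistical jitter and is configurable.
- **Pooling**: one fit per participant per condition uses all 84 trials
  (3 lists × 28); per-list fitting is exposed as an option
  (`fit(by_list=True)`) but is not the default, since weights are assumed
  invariant across decisions within a condition.
- Estimates are invariant to a common rescaling of all log-odds, and exact
  recovery holds at σ = 0; both are tested.

## Angular statistics

Weight vectors are compared by the angle `arccos` of the cosine
similarity, clipped to [−1, 1] to absorb floating-point overshoot.
Distances are scale-invariant; for componentwise-nonnegative vectors the
angle is at most π/2, attained only against an axis-parallel vector. The
raw cosine is also exposed for diagnostics.

Four summary statistics: overall weight change `D(k_N, k_Q)` (nonnegative,
cross-condition), self-weighting `D(k_j, ê_j)`, weight equality
`D(k, û)` with `û = (1,1,1)`, and weight similarity (the three pairwise
angles per triad). The last three enter condition contrasts as
noise-minus-quiet differences; positive values mean larger distances in
noise.

**Per-participant similarity.** Pairwise angles belong to pairs, not
participants. For participant-level summaries each pairwise angle is
attributed to both members, and a participant's scalar similarity value is
the mean of the two angles involving them (needed for one-value-per-
participant permutation testing); the per-pair values are also exported.
Averaging per member instead is available via `pair_mode`.

**Ternary export.** Weights are normalized to sum to one and projected
onto the 2-simplex (corners = pure weighting toward one member, centroid =
uniform); negative normalized components fall outside the triangle and
carry an `out_of_bounds` flag. Rendering is left to the user.

## Inference

- **Permutation unit**: whole trials. A trial carries the triad's three
  priors and three posteriors; shuffling condition labels over trials
  (preserving the 84/84 split) keeps the members' re-estimates aligned,
  which the pairwise similarity statistic requires, and is the finest
  exchangeable unit under the null of no condition effect. Shuffling whole
  lists (3 + 3) is available via `unit="list"` if one prefers to respect
  list structure.
- **p-values**: add-one rule `(b+1)/(m+1)`, never zero. One-tailed for
  overall weight change (nonnegative by construction), two-tailed via
  |permuted| ≥ |observed| around a null center of 0 for the difference
  statistics. Failed re-estimates inside a permutation are dropped and
  counted.
- **Pooling**: median across participants; optionally an intermediate
  median within groups first (guards against within-group dependence).
  The population null pools the aligned permutation draws the same way:
  draw m of the pooled null combines every triad's m-th shuffle.
- **Group level**: a group's statistic is the median of its three members,
  tested against the aligned permutation null of that median.
- **Bootstrap**: percentile 2.5–97.5% intervals. Participants are
  resampled at the population level. Three members are too few to
  resample, so group-level intervals resample trials within each condition
  and refit (`bootstrap_group_ci`); outputs are labelled with the unit
  used.
- **Sensitivity**: any population result can be recomputed with chosen
  groups excluded, reusing the same permutation draws.

## Synthetic data and the simulation studies

The generator reproduces the study design: 10 triads, conditions noise and
quiet, 3 lists per condition, 28 trials per list (all unordered pairs of 8
items), lists disjoint across conditions. True per-member, per-condition
weight vectors are supplied or sampled (components uniform on (0.1, 1.5)),
and posteriors are drawn from the model. Ground-truth condition effects
can be constructed exactly: `none` (identical weights), `rotate_by_angle`
(overall change equal to a requested angle, via rotation in the plane of
the weight and a random orthogonal direction), and `self_shift` (weights
moved toward each member's own axis in noise).

**Prior distribution.** The empirical prior distribution is not available
without the deposited dataset, so simulations use a generative stand-in:
the chosen option is uniform (sign ±1) and the confidence percent follows
a normal with mean 75 and SD 15 truncated to [50, 100] and capped at 99 —
a unimodal mid-high confidence profile typical of general-knowledge binary
questions. Mean and SD are configurable; an empirical-resampling mode is
the natural replacement once real data are loaded.

Three validation studies (all reproducible from config + seed):

1. **Parameter recovery**: k ~ U(0.1, 1.5) per component, σ = 1, at trial
   counts 84 / 252 / 2520 (per participant-condition, per group, per
   population — the design arithmetic). Estimates track truth with
   regression slope ≈ 1 and correlation > 0.8 at N = 84; error decreases
   in N and increases in σ.
2. **Distance validation**: each angular statistic is compared with a
   sign-only agreement index (self: posterior sign matches own prior sign;
   equality: matches the equally-weighted sum; similarity/overall change:
   two posterior sets from two weight draws agree). Run at σ = 1 and
   σ = 0.01; each distance correlates negatively with its index. Sign ties
   at C = 0 count as disagreement unless both sides are zero (an
   indifferent report expresses no decision).
3. **Reporting bias**: one member's *reported* prior log-odds are scaled
   by a slope (mild 0.75 / 1.33, extreme 0.5 / 2.0 — linear in log-odds
   through the origin, preserving indifference) before estimation, while
   posteriors are generated from unbiased values, at σ = 0.01. The
   algebra is transparent: scaling member b's reported prior by s scales
   the estimated weight toward b by 1/s. Underreporting by one member
   therefore biases *other* members' self-weighting distance upward (their
   degree of self-weighting is underestimated); equality errors split into
   over- and under-estimation depending on the weight configuration; and
   pairwise-distance errors grow in variance with bias severity. Each
   setting reuses the same random substream, and an unbiased estimate per
   draw is included, so slope = 1 reproduces it exactly.

**Type-I calibration.** On null synthetic triads (identical weights in
both conditions) the participant-level permutation tests reject at
α = 0.05 at the nominal rate for all four statistics. The calibration
check counts one participant per replicate triad: members of a triad share
trials and shuffles, so their test outcomes are dependent, and only
across-replicate outcomes form the independent Bernoulli sequence that an
exact binomial reference band requires.

### Problem sizes

The default simulation size is 1000 draws (the `validate` CLI command);
the test suite and the acceptance script use scaled-down but statistically
adequate sizes chosen once: 200 draws for the recovery, distance and bias
studies, 200 permutations × 50 replicates for calibration, and spot checks
rather than full grids for monotonicity properties.

## What passing tests do and do not show

The synthetic generator matches the experiment's design arithmetic and its
generative model — by construction, data simulated from the model are
ideally suited to the estimator. Passing recovery and calibration tests
therefore demonstrates the correctness and internal consistency of the
pipeline, not the adequacy of the model for real conversations: real data
add memory loss between discussion and decision, transitive inference
across related questions, agreement-dependent integration, and
idiosyncratic confidence-scale use, none of which the model represents.
The reporting-bias study quantifies the estimator's sensitivity to the
last of these. Analyses of real datasets should treat negative-weight
anomalies and reporting-bias magnitudes as empirical questions, using the
sensitivity-rerun and bias-study tools provided.

## Known limitations

- Triads only: the weight vector and geometry are dimensioned for three
  members (the model itself generalizes, the code does not).
- The permutation scheme assumes trial exchangeability between conditions
  within a participant; list-level structure can be respected via
  `unit="list"` but is not the default.
- Posterior log-odds beyond ±ln(99) cannot be expressed on the percent
  report scale; rendering simulated data to percent reports clips them
  (simulations keep unclipped values internally by default,
  `clip_posteriors=True` to bound them at generation).
- Group-level bootstrap intervals rest on a trial-resampling heuristic;
  with three members per group there is no nonparametric alternative at
  the member level.
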