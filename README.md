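# triadvote

Confidence-weighted voting analysis of triadic group decisions.

When three people discuss a set of binary questions and then privately
revise their answers, how much does each member's final decision lean on
their own initial judgement versus the judgements of the other two — and
does that weighting change when communication is made harder (for example
by loud background noise)? `triadvote` implements a complete statistical
pipeline for this question, aimed at researchers studying collaborative
decision-making, information exchange in conversation, and communication
under adverse conditions (hearing research, group cognition, speech in
noise).

## The model

Each answer is a choice between two options plus a confidence rating on a
50–100% scale. Folding choice and confidence into a single signed
probability `c` toward a canonical option, the rating becomes a log-odds
confidence `C = ln(c / (1 − c))`; `C = 0` is indifference and the sign
encodes the chosen option. Ratings of 100% are truncated to 99%, capping
|C| at ln(99) ≈ 4.60.

Member *j*'s post-discussion (posterior) confidence on a trial is modelled
as a noisy weighted sum of the three prior confidences — an
individual-response extension of confidence-weighted majority voting:

    C_j^p ~ N( Σ_{i ∈ {a,b,c}} k_{j,i} · C_i ,  σ )

The weight `k_{j,i}` measures how much member *j* is influenced by member
*i*'s prior judgement (including *i* = *j*: self-weighting). Given N
trials, the maximum-likelihood weight vector solves the 3×3 normal
equations

    ( Σ_n C_n C_nᵀ ) k_j = Σ_n C_n C_{j,n}^p

in closed form, with σ̂ = √(RSS/N). Weights are fitted separately per
participant and condition.

Because only the *direction* of a weight vector is meaningful for how
information is combined, condition effects are summarized by angles
(radians) between weight vectors, `D(x, y) = arccos(x·y/|x||y|)`:

- **overall weight change** — angle between a participant's two condition
  fits (nonnegative; π/2 is the maximum for nonnegative weights);
- **self-weighting** — angle to the member's own axis (small = posterior
  tracks own prior);
- **weight equality** — angle to the uniform vector (1,1,1), the optimal
  weighting for calibrated confidences;
- **weight similarity** — pairwise angles between the members of a triad.

Condition contrasts are tested by shuffling condition labels within each
triad and re-estimating (permutation test; one-tailed for the nonnegative
overall change, two-tailed otherwise), pooled as medians across
participants (optionally via group medians), with percentile-bootstrap
95% intervals.

## Worked example

Generate a synthetic study with the experiment's design (10 triads × 2
conditions × 3 lists × 28 binary questions) in which every member's true
weights are rotated by exactly 0.42 rad between conditions, then fit and
test:

```python
import numpy as np
from triadvote import GroupDecisionModel, generate_study
from triadvote.synthetic import StudyDesign, sample_weight_table, make_condition_effect

rng = np.random.default_rng(42)
design = StudyDesign()
base = (sample_weight_table(design, rng).query("condition == 'quiet'")
        .drop(columns="condition").reset_index(drop=True))
weights = make_condition_effect(base, effect="rotate_by_angle", magnitude=0.42, rng=rng)
trials, truth = generate_study(design, weights=weights, sigma=1.0, rng=rng)

res = GroupDecisionModel(trials).fit()
print(res.summary())
tables = res.permutation_test(n_permutations=1000, n_bootstrap=1000, seed=42)
print(tables["population"][["statistic", "observed", "p", "ci_low", "ci_high"]]
      .round(4).to_string(index=False))
```

```
Confidence-weighted voting model — fitted weights
==========================================================
Groups:  10    participants:  30    weight vectors:   60
Conditions: noise, quiet    trials per fit (median): 84
Residual SD sigma (median [min, max]): 0.967 [0.817, 1.188]
Weight vectors with a negative component: 11
----------------------------------------------------------
Population medians (noise-minus-quiet where applicable):
  overall_change     +0.4233 rad
  self_weighting     +0.1885 rad
  weight_equality    +0.2253 rad
  weight_similarity  +0.3259 rad

        statistic  observed     p  ci_low  ci_high
   overall_change    0.4233 0.001  0.3905   0.4419
   self_weighting    0.1885 0.001 -0.0948   0.2546
  weight_equality    0.2253 0.001  0.0856   0.3033
weight_similarity    0.3259 0.001  0.1513   0.4312
```

The fitted residual SD recovers the generating σ = 1, and the population
median overall change (0.4233 rad, CI [0.39, 0.44]) recovers the true
0.42 rad rotation; the permutation p of 0.001 is the smallest attainable
at 1000 permutations with the add-one rule. The positive medians of the
other three statistics say distances were larger in the noise condition —
i.e. less self-anchoring, less equal and less mutually similar weighting
in quiet, as expected when every member's weights were rotated.

The same pipeline runs from the shell on any trial CSV (including a
schema-mapped export of a real dataset):

```bash
triadvote simulate --seed 42 -o run/
triadvote fit run/trials.csv -o run/
triadvote test run/trials.csv --seed 42 --n-permutations 10000 -o run/
triadvote report run/trials.csv --seed 42 -o run/
```

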