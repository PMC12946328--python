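"""Angular geometry of influence-weight vectors.

Distances between weight vectors are measured as the angle (in radians)
between them, ``D(x, y) = arccos( x.y / (|x||y|) )`` — scale-invariant, so
only the *direction* of weighting matters.  For vectors with nonnegative
components the angle is at most pi/2, attained only when one vector lies on
an axis.  Four summary statistics build on this distance:

- overall weight change: angle between one participant's weight vectors
  fitted in the two conditions;
- self-weighting: angle between a member's weights and their own axis (low
  angle = posterior decisions track the member's own prior);
- weight equality: angle to the uniform vector (1, 1, 1), the optimal
  weighting when confidences are calibrated correctness probabilities;
- weight similarity: pairwise angles between the members of a triad.
"""

from __future__ import annotations

import numpy as np

from .decision import MEMBERS, WeightVector

__all__ = [
    "angular_distance",
    "cosine_similarity",
    "overall_weight_change",
    "self_weighting",
    "weight_equality",
    "weight_similarity",
    "condition_difference",
    "ternary_coordinates",
    "UNIFORM",
]

#: The equal-weighting direction.
UNIFORM = np.ones(3)

#: Axis unit vector per member.
AXES = {m: np.eye(3)[i] for i, m in enumerate(MEMBERS)}

#: The three unordered member pairs, in canonical order.
PAIRS = (("a", "b"), ("a", "c"), ("b", "c"))


class UndefinedAngleError(ValueError):
    """Angle requested against a zero-length weight vector."""


def _vec(x) -> np.ndarray:
    v = np.asarray(x.k if isinstance(x, WeightVector) else x, dtype=float)
    return v


def cosine_similarity(x, y) -> float:
    """Raw cosine ``x.y / (|x||y|)``, clipped to [-1, 1]."""
    x, y = _vec(x), _vec(y)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise UndefinedAngleError("angle undefined for a zero-length weight vector")
    return float(np.clip((x @ y) / (nx * ny), -1.0, 1.0))


def angular_distance(x, y) -> float:
    """Angle between two weight vectors, in radians (in [0, pi])."""
    return float(np.arccos(cosine_similarity(x, y)))


def overall_weight_change(k_noise, k_quiet) -> float:
    """Angle between one participant's noise- and quiet-condition weights."""
    return angular_distance(k_noise, k_quiet)


def self_weighting(w: WeightVector, owner: str | None = None) -> float:
    """Angle between a member's weights and their own axis.

    ``owner`` defaults to ``w.owner`` when a :class:`WeightVector` is given;
    it must be supplied for a bare array.
    """
    if owner is None:
        if not isinstance(w, WeightVector):
            raise ValueError("owner must be given when w is a bare array")
        owner = w.owner
    return angular_distance(w, AXES[owner])


def weight_equality(w) -> float:
    """Angle to the uniform vector (1, 1, 1); zero means equal weighting."""
    return angular_distance(w, UNIFORM)


def weight_similarity(weights) -> dict:
    """Pairwise angles between the three members' weight vectors.

    ``weights`` maps member labels to weight vectors (or is a (3, 3) array
    with rows in member order).  Returns ``{("a","b"): angle, ...}`` for the
    three unordered pairs.
    """
    if isinstance(weights, np.ndarray):
        weights = {m: weights[i] for i, m in enumerate(MEMBERS)}
    return {(i, j): angular_distance(weights[i], weights[j]) for i, j in PAIRS}


def condition_difference(stat_noise: float, stat_quiet: float) -> float:
    """Noise-minus-quiet difference; positive = larger distance in noise."""
    return stat_noise - stat_quiet


# Ternary corners for members a, b, c: an equilateral triangle of unit side.
_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


def ternary_coordinates(w):
    """Project a weight vector onto the plane ``k_a + k_b + k_c = 1``.

    The vector is normalised to sum to one and mapped to planar coordinates
    of an equilateral triangle whose corners (a, b, c) represent pure
    weighting toward a single member and whose centroid is the uniform
    weight.  A negative normalised component places the point outside the
    simplex; the returned flag marks that case.

    Returns
    -------
    (xy, out_of_bounds) : (ndarray shape (2,), bool)
    """
    v = _vec(w)
    total = v.sum()
    if total == 0.0:
        raise UndefinedAngleError("ternary coordinates undefined for a zero-sum vector")
    p = v / total
    return p @ _CORNERS, bool(np.any(p < 0))
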