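"""Angular distances, the four summary statistics, and ternary projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triadvote.decision import WeightVector
from triadvote.geometry import (UndefinedAngleError, angular_distance, condition_difference,
                                cosine_similarity, overall_weight_change, self_weighting,
                                ternary_coordinates, weight_equality, weight_similarity)

ANGLE_CASES = [
    ((0.4, 1.1, 0.2), (0.4, 1.1, 0.2), 0.0),
    ((1, 0, 0), (0, 1, 0), np.pi / 2),
    ((1, 1, 1), (1, 1, 0), np.arccos(2 / np.sqrt(6))),
    ((1, 1, 1), (1, 0, 0), np.arccos(1 / np.sqrt(3))),
    ((1, 1, 0), (1, 0, 0), np.arccos(1 / np.sqrt(2))),
]


@pytest.mark.parametrize("x,y,expected", ANGLE_CASES)
def test_closed_form_angles(x, y, expected):
    assert angular_distance(np.array(x, float), np.array(y, float)) == pytest.approx(expected)
    assert overall_weight_change(np.array(x, float), np.array(y, float)) == pytest.approx(expected)


def test_zero_vector_rejected():
    with pytest.raises(UndefinedAngleError):
        angular_distance(np.zeros(3), np.ones(3))


def test_cosine_clipped_against_float_overshoot():
    v = np.array([1.0, 1.0, 1.0]) * (1 + 1e-16)
    assert cosine_similarity(v, v) == 1.0
    assert angular_distance(v, v) == 0.0


unit_vec = st.tuples(*[st.floats(min_value=0.01, max_value=2.0)] * 3)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(unit_vec, unit_vec, st.floats(min_value=0.01, max_value=100.0))
def test_scale_invariance(x, y, s):
    x, y = np.array(x), np.array(y)
    # arccos amplifies float error near 0 by ~1/sqrt(eps), hence the loose abs
    assert angular_distance(s * x, y) == pytest.approx(angular_distance(x, y), abs=1e-6)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(unit_vec, unit_vec)
def test_nonnegative_vectors_stay_within_quarter_turn(x, y):
    assert angular_distance(np.array(x), np.array(y)) <= np.pi / 2 + 1e-12


def test_quarter_turn_needs_an_axis_vector():
    # the pi/2 maximum for nonnegative weights is attained only against an axis
    assert angular_distance(np.array([1.0, 0, 0]), np.array([0.0, 2, 3])) == pytest.approx(np.pi / 2)
    assert angular_distance(np.array([1.0, 0.1, 0]), np.array([0.0, 2, 3])) < np.pi / 2


class TestSelfWeighting:
    @pytest.mark.parametrize("k,expected", [
        ((1, 0, 0), 0.0),
        ((0, 1, 1), np.pi / 2),
        ((1, 1, 1), np.arccos(1 / np.sqrt(3))),
    ])
    def test_owner_a(self, k, expected):
        w = WeightVector("a", np.array(k, float))
        assert self_weighting(w) == pytest.approx(expected)

    def test_owner_required_for_bare_arrays(self):
        assert self_weighting(np.array([0.0, 1, 0]), "b") == 0.0
        with pytest.raises(ValueError):
            self_weighting(np.array([1.0, 0, 0]))


@pytest.mark.parametrize("k,expected", [
    ((2, 2, 2), 0.0),
    ((1, 0, 0), np.arccos(1 / np.sqrt(3))),
    ((1, 1, 0), np.arccos(2 / np.sqrt(6))),
])
def test_weight_equality(k, expected):
    assert weight_equality(np.array(k, float)) == pytest.approx(expected)


class TestSimilarity:
    def test_identical_weights(self):
        K = np.tile([0.3, 0.4, 0.5], (3, 1))
        assert list(weight_similarity(K).values()) == pytest.approx([0, 0, 0], abs=1e-6)

    def test_axis_aligned_members(self):
        assert list(weight_similarity(np.eye(3)).values()) == pytest.approx([np.pi / 2] * 3)

    def test_mixed_closed_forms(self):
        K = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]], dtype=float)
        vals = weight_similarity(K)
        assert vals[("a", "b")] == pytest.approx(np.arccos(2 / np.sqrt(6)))
        assert vals[("a", "c")] == pytest.approx(np.arccos(1 / np.sqrt(3)))
        assert vals[("b", "c")] == pytest.approx(np.arccos(1 / np.sqrt(2)))


def test_member_relabeling_symmetry(rng):
    """A consistent member permutation preserves change, equality, and the similarity multiset."""
    K1 = rng.uniform(0.1, 1.5, (3, 3))
    K2 = rng.uniform(0.1, 1.5, (3, 3))
    perm = np.array([2, 0, 1])
    K1p, K2p = K1[perm][:, perm], K2[perm][:, perm]
    for i in range(3):
        assert angular_distance(K1p[i], K2p[i]) == pytest.approx(
            angular_distance(K1[perm[i]], K2[perm[i]]))
        assert weight_equality(K1p[i]) == pytest.approx(weight_equality(K1[perm[i]]))
    orig = sorted(weight_similarity(K1).values())
    relab = sorted(weight_similarity(K1p).values())
    assert relab == pytest.approx(orig)


@pytest.mark.parametrize("noise,quiet,expected", [(0.9, 0.9, 0.0), (1.0, 0.6, 0.4), (0.5, 0.7, -0.2)])
def test_condition_difference_sign_convention(noise, quiet, expected):
    assert condition_difference(noise, quiet) == pytest.approx(expected)


class TestTernary:
    def test_uniform_maps_to_centroid(self):
        xy, out = ternary_coordinates(np.array([1.0, 1, 1]))
        assert xy == pytest.approx([0.5, np.sqrt(3) / 6])
        assert not out

    def test_pure_weight_maps_to_corner(self):
        xy, out = ternary_coordinates(np.array([3.0, 0, 0]))
        assert xy == pytest.approx([0.0, 0.0])
        assert not out

    def test_negative_component_flags_out_of_bounds(self):
        _, out = ternary_coordinates(np.array([1.2, -0.2, 1.0]))
        assert out

    def test_zero_sum_rejected(self):
        with pytest.raises(UndefinedAngleError):
            ternary_coordinates(np.array([1.0, -1.0, 0.0]))
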