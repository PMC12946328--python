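"""Permutation tests, pooling, bootstrap intervals, sensitivity reruns."""

import numpy as np
import pandas as pd
import pytest

from triadvote.inference import (STATISTICS, bootstrap_ci, full_analysis, permutation_p,
                                 permute_triad, pool, population_null, run_permutation_tests,
                                 sensitivity_rerun)
from triadvote.synthetic import StudyDesign, generate_study, make_condition_effect


class TestPool:
    def test_plain_median(self):
        assert pool([0.1, 0.4, 0.2]) == pytest.approx(0.2)

    def test_intermediate_pooling(self):
        vals = [0.1, 0.1, 0.9, 0.5]
        groups = ["g1", "g1", "g1", "g2"]
        assert pool(vals, intermediate=True, groups=groups) == pytest.approx(0.3)
        assert pool(vals) == pytest.approx(0.3)  # coincides here

    def test_intermediate_equals_plain_for_singleton_groups(self, rng):
        vals = rng.normal(size=7)
        groups = [f"g{i}" for i in range(7)]
        assert pool(vals, intermediate=True, groups=groups) == pytest.approx(pool(vals))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool([])


class TestPermutationP:
    def test_add_one_extreme(self):
        null = np.zeros(200)
        assert permutation_p(0.5, null, "one") == pytest.approx(1 / 201)

    def test_degenerate_null(self):
        assert permutation_p(0.0, np.zeros(200), "one") == pytest.approx(1.0)

    def test_two_tailed_uses_magnitude(self):
        null = np.array([-3.0, -2.0, 1.0, 0.5])
        assert permutation_p(-1.5, null, "two") == pytest.approx(3 / 5)


def test_zero_permutations_rejected(null_study, rng):
    trials, _ = null_study
    triad = trials[trials["group"] == "A"]
    with pytest.raises(ValueError):
        permute_triad(triad, 0, rng)


def test_permutation_detects_orthogonal_weight_change(rng):
    """Extreme condition effect: axis-orthogonal weights, near-noiseless data."""
    rows = []
    for member, kq, kn in zip("abc", np.eye(3), np.roll(np.eye(3), 1, axis=0)):
        rows.append({"group": "A", "member": member, "condition": "quiet",
                     "k_a": kq[0], "k_b": kq[1], "k_c": kq[2]})
        rows.append({"group": "A", "member": member, "condition": "noise",
                     "k_a": kn[0], "k_b": kn[1], "k_c": kn[2]})
    weights = pd.DataFrame(rows)
    hits = 0
    for rep in range(10):
        trials, _ = generate_study(StudyDesign(n_groups=1), weights=weights, sigma=0.1,
                                   rng=np.random.default_rng(100 + rep))
        triad = trials[trials["group"] == "A"]
        observed, null, _ = permute_triad(triad, 200, np.random.default_rng(rep))
        p = permutation_p(float(observed["overall_change"][0]),
                          null["overall_change"][:, 0], "one")
        hits += p < 0.05
    assert hits >= 9  # detected in (essentially) every replicate


class TestBootstrap:
    def test_zero_variance(self, rng):
        lo, hi = bootstrap_ci(np.full(10, 0.3), n_boot=500, rng=rng)
        assert (lo, hi) == (pytest.approx(0.3), pytest.approx(0.3))

    def test_brackets_the_median(self, rng):
        vals = np.arange(0.1, 1.01, 0.1)
        lo, hi = bootstrap_ci(vals, n_boot=2000, rng=rng)
        assert lo < np.median(vals) < hi

    def test_small_n_boot_warns(self, rng):
        with pytest.warns(UserWarning):
            bootstrap_ci(np.arange(5.0), n_boot=50, rng=rng)

    def test_single_value_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_ci([0.3], rng=rng)


class TestPopulationNull:
    def test_degenerate(self):
        obs = np.zeros(6)
        null = np.zeros((200, 6))
        pooled, null_pooled, p = population_null(obs, null, "overall_change")
        assert pooled == 0.0 and p == pytest.approx(1.0)

    def test_extreme_observed(self):
        obs = np.full(6, 2.0)
        null = np.zeros((200, 6))
        _, _, p = population_null(obs, null, "overall_change")
        assert p == pytest.approx(1 / 201)

    def test_misaligned_draws_rejected(self):
        with pytest.raises(ValueError):
            population_null(np.zeros(4), np.zeros((10, 5)), "overall_change")


@pytest.fixture(scope="module")
def tables(null_study):
    trials, _ = null_study
    return full_analysis(trials, n_perm=100, n_boot=200, rng=np.random.default_rng(2))


@pytest.fixture(scope="module")
def outcome(null_study):
    trials, _ = null_study
    return run_permutation_tests(trials, n_perm=50, rng=np.random.default_rng(4))


class TestFullAnalysis:
    def test_all_levels_reported(self, tables):
        assert set(tables) >= {"participant", "group", "population", "population_intermediate"}
        assert len(tables["participant"]) == 9 * 4  # 3 triads x 3 members x 4 stats
        assert len(tables["group"]) == 3 * 4
        assert set(tables["population"]["statistic"]) == set(STATISTICS)

    def test_p_values_valid(self, tables):
        for name in ("participant", "group", "population"):
            p = tables[name]["p"]
            assert ((p > 0) & (p <= 1)).all()

    def test_overall_change_nonnegative(self, tables):
        part = tables["participant"]
        assert (part.query("statistic == 'overall_change'")["observed"] >= 0).all()


class TestSensitivity:
    def test_empty_exclusion_is_identity(self, outcome, rng):
        full = sensitivity_rerun(outcome, set(), n_boot=200, rng=np.random.default_rng(9))
        base = sensitivity_rerun(outcome, set(), n_boot=200, rng=np.random.default_rng(9))
        pd.testing.assert_frame_equal(full, base)
        assert (full["n_participants"] == 9).all()

    def test_exclusion_count_arithmetic(self, outcome, rng):
        reduced = sensitivity_rerun(outcome, {"A"}, n_boot=200, rng=rng)
        assert (reduced["n_participants"] == 6).all()

    def test_excluding_everything_rejected(self, outcome, rng):
        with pytest.raises(ValueError):
            sensitivity_rerun(outcome, {"A", "B", "C"}, n_boot=200, rng=rng)

    def test_unknown_group_rejected(self, outcome, rng):
        with pytest.raises(ValueError):
            sensitivity_rerun(outcome, {"Z"}, n_boot=200, rng=rng)


def test_effect_confined_to_excluded_groups_disappears(rng):
    """If only two groups carry the condition effect, removing them removes significance."""
    from triadvote.synthetic import sample_weight_table

    design = StudyDesign(n_groups=4)
    gen = np.random.default_rng(21)
    base = (sample_weight_table(design, gen).query("condition == 'quiet'")
            .drop(columns="condition").reset_index(drop=True))
    null_w = make_condition_effect(base, effect="none")
    eff_w = make_condition_effect(base, effect="rotate_by_angle", magnitude=1.2, rng=gen)
    weights = pd.concat([eff_w[eff_w["group"].isin(["A", "B"])],
                         null_w[~null_w["group"].isin(["A", "B"])]], ignore_index=True)
    trials, _ = generate_study(design, weights=weights, sigma=0.3, rng=gen)
    outcome = run_permutation_tests(trials, n_perm=200, rng=np.random.default_rng(5))
    with_eff = sensitivity_rerun(outcome, set(), n_boot=200, rng=np.random.default_rng(6))
    without = sensitivity_rerun(outcome, {"A", "B"}, n_boot=200, rng=np.random.default_rng(6))
    p_with = float(with_eff.set_index("statistic").loc["overall_change", "p"])
    p_without = float(without.set_index("statistic").loc["overall_change", "p"])
    assert p_with < 0.05 < p_without


def test_list_level_shuffling_runs(null_study):
    trials, _ = null_study
    triad = trials[trials["group"] == "A"]
    observed, null, n_failed = permute_triad(triad, 20, np.random.default_rng(0), unit="list")
    assert null["overall_change"].shape == (20, 3)
    assert n_failed == 0
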