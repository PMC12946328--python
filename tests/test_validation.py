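"""The three validation simulations: recovery, distance metrics, reporting bias."""

import numpy as np
import pytest

from triadvote.estimation import solve_weights
from triadvote.validation import (BiasMap, SimulationConfig, agreement_index,
                                  run_bias_study, run_distance_validation,
                                  run_parameter_recovery, sample_priors, sample_weight)


def test_priors_respect_the_confidence_scale(rng):
    X = sample_priors(2000, rng)
    mags = np.abs(X)
    assert mags.max() <= np.log(99.0) + 1e-12
    assert mags.min() >= 0.0  # 50% maps to zero log-odds
    # signs are balanced
    assert abs(np.mean(X > 0) - 0.5) < 0.05


def test_noiseless_recovery_is_exact(rng):
    k = sample_weight(rng)
    X = sample_priors(84, rng)
    k_hat, *_ = solve_weights(X, X @ k)
    np.testing.assert_allclose(k_hat, k, atol=1e-8)


def test_recovery_error_shrinks_with_trials_and_grows_with_noise():
    """Median component error is monotone in N (down) and in sigma (up)."""
    rng = np.random.default_rng(8)
    med_err = {}
    for sigma in (0.5, 2.0):
        for n in (30, 300):
            errs = []
            for _ in range(150):
                k = sample_weight(rng)
                X = sample_priors(n, rng)
                y = X @ k + rng.normal(0, sigma, n)
                k_hat, *_ = solve_weights(X, y)
                errs.append(np.abs(k_hat - k).mean())
            med_err[(sigma, n)] = np.median(errs)
    assert med_err[(0.5, 300)] < med_err[(0.5, 30)]
    assert med_err[(2.0, 300)] < med_err[(2.0, 30)]
    assert med_err[(0.5, 30)] < med_err[(2.0, 30)]
    assert med_err[(0.5, 300)] < med_err[(2.0, 300)]


def test_recovery_table_shape_and_reproducibility():
    cfg = SimulationConfig(n_draws=5, seed=42)
    t1 = run_parameter_recovery(cfg, scales=(84, 252))
    t2 = run_parameter_recovery(cfg, scales=(84, 252))
    assert t1.equals(t2)
    assert len(t1) == 5 * 2 * 3  # draws x scales x components


def test_rmse_smaller_at_population_scale():
    cfg = SimulationConfig(n_draws=60, seed=13)
    tab = run_parameter_recovery(cfg, scales=(84, 2520))
    rmse = tab.assign(err=(tab["estimated"] - tab["true"]) ** 2).groupby("n_trials")["err"].mean() ** 0.5
    assert rmse[2520] < rmse[84]


class TestAgreementIndex:
    def test_pure_self_weighting_gives_full_agreement(self, rng):
        X = sample_priors(100, rng)
        y = X @ np.eye(3)[0]  # member a copies their own prior, sigma = 0
        assert agreement_index(y, "self", prior=X[:, 0]) == 1.0

    def test_uniform_weights_give_full_equality_agreement(self, rng):
        X = sample_priors(100, rng)
        y = X @ np.ones(3)
        assert agreement_index(y, "equality", prior=X) == 1.0

    def test_identical_decision_makers_agree(self, rng):
        X = sample_priors(100, rng)
        y = X @ sample_weight(rng)
        assert agreement_index(y, "similarity", posterior2=y.copy()) == 1.0

    def test_one_sided_tie_counts_as_disagreement(self):
        assert agreement_index([0.0, 1.0], "similarity", posterior2=[1.0, 1.0]) == 0.5
        assert agreement_index([0.0, 0.0], "similarity", posterior2=[0.0, -1.0]) == 0.5

    def test_unknown_flavor_rejected(self):
        with pytest.raises(ValueError):
            agreement_index([1.0], "bogus")


def test_distance_validation_recovers_distances_at_low_noise():
    cfg = SimulationConfig(n_draws=100, seed=5)
    tab = run_distance_validation(cfg, sigmas=(0.01,))
    for metric, sub in tab.groupby("metric"):
        r = np.corrcoef(sub["true_distance"], sub["est_distance"])[0, 1]
        assert r > 0.9, f"{metric}: estimated-vs-true correlation {r:.3f}"


class TestBiasStudy:
    def test_identity_slope_reproduces_unbiased_estimates(self):
        cfg = SimulationConfig(n_draws=20, sigma=0.01, seed=3)
        tab = run_bias_study(cfg, bias_settings=(BiasMap(1.0, "identity"),))
        np.testing.assert_array_equal(tab["est_distance"], tab["est_unbiased_distance"])

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            BiasMap(0.0, "zero")
        with pytest.raises(ValueError):
            run_bias_study(SimulationConfig(n_draws=2), bias_settings=())

    def test_equality_errors_split_both_ways_under_extreme_bias(self):
        """Extreme bias drives equality estimates both above and below truth."""
        cfg = SimulationConfig(n_draws=150, sigma=0.01, seed=6)
        tab = run_bias_study(cfg, bias_settings=(BiasMap(0.5, "extreme_under"),))
        eq = tab.query("metric == 'weight_equality'")
        err = eq["est_distance"] - eq["true_distance"]
        assert (err > 0.01).any() and (err < -0.01).any()


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(k_low=1.0, k_high=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_trials=2)
    with pytest.raises(ValueError):
        SimulationConfig(n_draws=0)
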