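"""Three-stage X-Learner: pseudo-outcomes, staging, combination and
recovery against the generator's ground truth."""

import numpy as np
import pytest

from paxlearn import (
    ConstantModel,
    PositivityError,
    PropensityModel,
    ValidationError,
    combine_cate,
    compute_pseudo_outcomes,
    estimate_cate,
    fit_propensity,
    fit_stage1,
    fit_stage2,
    summarize_effect,
)
from paxlearn.synthetic import EffectSpec, recovery_config
from paxlearn.xlearner import OutcomeModelPair
from conftest import aligned_arrays


class LookupModel:
    """Probability model keyed on the first feature value."""

    def __init__(self, table):
        self.table = table

    def predict_probability(self, X):
        return np.array([self.table[x0] for x0 in np.asarray(X)[:, 0]])


class TestPseudoOutcomes:
    def test_four_unit_hand_example(self):
        # treated: (Y=1, mu0=0.2) -> 0.8 ; (Y=0, mu0=0.5) -> -0.5
        # control: (Y=0, mu1=0.7) -> 0.7 ; (Y=1, mu1=0.4) -> -0.6
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        t = np.array([1, 1, 0, 0])
        y = np.array([1, 0, 0, 1])
        pair = OutcomeModelPair(
            mu1=LookupModel({3.0: 0.7, 4.0: 0.4, 1.0: 0.9, 2.0: 0.9}),
            mu0=LookupModel({1.0: 0.2, 2.0: 0.5, 3.0: 0.1, 4.0: 0.1}),
        )
        pseudo = compute_pseudo_outcomes(pair, X, t, y)
        np.testing.assert_allclose(pseudo.D1, [0.8, -0.5])
        np.testing.assert_allclose(pseudo.D0, [0.7, -0.6])

    def test_perfectly_predicted_counterfactual_gives_zero_effect(self):
        X = np.array([[0.0], [1.0]])
        pair = OutcomeModelPair(
            mu1=ConstantModel(1.0), mu0=LookupModel({0.0: 1.0, 1.0: 1.0})
        )
        pseudo = compute_pseudo_outcomes(pair, X, np.array([1, 0]), np.array([1, 1]))
        assert pseudo.D1[0] == pytest.approx(0.0)

    def test_values_stay_inside_unit_interval_for_binary_outcomes(self, recovery_run):
        X, t, y, _, _ = recovery_run
        pair = fit_stage1(X, t, y, tag="logistic", seed=0)
        pseudo = compute_pseudo_outcomes(pair, X, t, y)
        assert np.all(np.abs(pseudo.D1) <= 1)
        assert np.all(np.abs(pseudo.D0) <= 1)

    def test_missing_arm_label_raises(self):
        pair = OutcomeModelPair(mu1=ConstantModel(0.5), mu0=ConstantModel(0.5))
        with pytest.raises(ValidationError):
            compute_pseudo_outcomes(
                pair, np.zeros((2, 1)), np.array([1, 2]), np.array([0, 1])
            )


class TestStage1:
    def test_single_class_arm_falls_back_to_clipped_constant(self):
        X = np.random.default_rng(0).normal(size=(40, 2))
        t = np.array([1] * 20 + [0] * 20)
        y = np.array([0] * 20 + [1, 0] * 10)
        pair = fit_stage1(X, t, y)
        assert isinstance(pair.mu1, ConstantModel)
        assert np.allclose(pair.mu1.predict_probability(X), 1e-6)

    def test_swapping_arm_labels_swaps_the_model_roles(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        t = (rng.random(200) < 0.5).astype(int)
        y = (rng.random(200) < 0.4).astype(int)
        a = fit_stage1(X, t, y, seed=0)
        b = fit_stage1(X, 1 - t, y, seed=0)
        np.testing.assert_allclose(
            a.mu1.predict_probability(X), b.mu0.predict_probability(X)
        )

    def test_empty_arm_is_a_positivity_error(self):
        with pytest.raises(PositivityError):
            fit_stage1(np.zeros((5, 1)), np.ones(5, dtype=int), np.zeros(5))

    def test_control_model_tracks_the_true_baseline_risk(self, recovery_run):
        X, t, y, truth, _ = recovery_run
        pair = fit_stage1(X, t, y, tag="logistic", seed=0)
        mu0 = pair.mu0.predict_probability(X)
        assert np.mean(np.abs(mu0 - truth.outcomes["depression"]["p0"])) <= 0.02


class TestStage2:
    def test_constant_pseudo_outcomes_give_a_constant_effect_model(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        from paxlearn.xlearner import PseudoOutcomeSet

        pseudo = PseudoOutcomeSet(
            D1=np.full(25, 0.1), D0=np.full(25, 0.1),
            treated_idx=np.arange(25), control_idx=np.arange(25, 50),
        )
        tau1, tau0 = fit_stage2(pseudo, X, tag="logistic")
        np.testing.assert_allclose(tau1.predict(rng.normal(size=(5, 3))), 0.1,
                                   atol=1e-9)

    def test_constant_effect_is_recovered_by_the_effect_regressor(self, recovery_run):
        X, t, y, truth, _ = recovery_run
        pair = fit_stage1(X, t, y, seed=0)
        pseudo = compute_pseudo_outcomes(pair, X, t, y)
        tau1, tau0 = fit_stage2(pseudo, X, seed=0)
        # raw convention: treatment lowers risk, so predictions near -0.1
        assert np.mean(tau1.predict(X)) == pytest.approx(-0.1, abs=0.02)

    def test_linear_in_age_effect_is_tracked_in_rank_order(self):
        cfg = recovery_config(0.1, seed=8, n=20000)
        cfg.true_effect = EffectSpec("linear", value=0.1, slope=0.05, feature="age")
        X, t, y, truth, _ = aligned_arrays(cfg)
        est = estimate_cate(X, t, y, base_model="logistic", seed=1, split=0.2)
        from scipy.stats import spearmanr

        tau_true = truth.outcomes["depression"]["tau"][est.index]
        rho = spearmanr(-est.tau_hat, tau_true).statistic
        assert rho >= 0.5


class TestPropensity:
    def test_random_assignment_yields_a_flat_half_propensity(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10000, 4))
        t = (rng.random(10000) < 0.5).astype(int)
        g = fit_propensity(X, t).predict(X)
        assert abs(g.mean() - 0.5) < 0.02

    def test_confounded_assignment_coefficients_are_recovered(self, recovery_run):
        X, t, y, truth, _ = recovery_run
        prop = fit_propensity(X, t, seed=0)
        g = prop.predict(X)
        # calibration against the generator's true propensity
        assert np.mean(np.abs(g - truth.g)) < 0.02

    def test_outputs_respect_the_clip_bounds(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(500, 1)) * 10
        t = (X[:, 0] + rng.normal(size=500) * 0.3 > 0).astype(int)
        g = fit_propensity(X, t, clip=(0.05, 0.95)).predict(X)
        assert g.min() >= 0.05 and g.max() <= 0.95

    def test_perfect_separation_falls_back_to_the_arm_share(self):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        t = (X[:, 0] > 0).astype(int)
        with pytest.warns(UserWarning, match="separates"):
            prop = fit_propensity(X, t)
        assert prop.constant == pytest.approx(0.5)


class TestCombination:
    def test_hand_arithmetic_of_the_convex_combination(self):
        X = np.zeros((1, 1))
        est = combine_cate(
            ConstantPredictor(0.6), ConstantPredictor(0.2),
            PropensityModel(None, constant=0.3), X,
        )
        assert est.tau_hat[0] == pytest.approx(0.3 * 0.2 + 0.7 * 0.6)

    def test_zero_propensity_weight_selects_tau1(self):
        X = np.zeros((3, 1))
        est = combine_cate(
            ConstantPredictor(0.4), ConstantPredictor(-0.9),
            PropensityModel(None, constant=0.0, clip=(0.0, 1.0)), X,
        )
        np.testing.assert_allclose(est.tau_hat, 0.4)

    def test_agreeing_effect_models_are_invariant_to_the_weight(self):
        X = np.zeros((3, 1))
        for g in (0.1, 0.5, 0.9):
            est = combine_cate(
                ConstantPredictor(0.25), ConstantPredictor(0.25),
                PropensityModel(None, constant=g), X,
            )
            np.testing.assert_allclose(est.tau_hat, 0.25)

    def test_combined_effect_lies_between_the_two_components(self, recovery_run):
        X, t, y, _, _ = recovery_run
        est = estimate_cate(X, t, y, base_model="logistic", seed=0)
        lo = np.minimum(est.tau0, est.tau1)
        hi = np.maximum(est.tau0, est.tau1)
        assert np.all(est.tau_hat >= lo - 1e-12)
        assert np.all(est.tau_hat <= hi + 1e-12)
        assert np.all(np.abs(est.tau_hat) <= 1)


class ConstantPredictor:
    def __init__(self, c):
        self.c = c

    def predict(self, X):
        return np.full(len(X), self.c)


def test_full_pipeline_matches_brute_force_on_a_tiny_cohort():
    """With constant-output components on identical covariate rows the
    pipeline ATE equals hand arithmetic exactly."""
    X = np.ones((8, 2))
    t = np.array([1, 1, 1, 0, 0, 0, 0, 0])
    y = np.array([1, 0, 1, 0, 1, 0, 0, 1])
    pair = OutcomeModelPair(mu1=ConstantModel(0.6), mu0=ConstantModel(0.25))
    pseudo = compute_pseudo_outcomes(pair, X, t, y)
    # D1 = y_treated - 0.25 ; D0 = 0.6 - y_control
    np.testing.assert_allclose(pseudo.D1, [0.75, -0.25, 0.75])
    np.testing.assert_allclose(pseudo.D0, [0.6, -0.4, 0.6, 0.6, -0.4])
    tau1, tau0 = fit_stage2(pseudo, X, tag="logistic")
    g = 3 / 8
    est = combine_cate(tau1, tau0, PropensityModel(None, constant=g), X)
    expected = g * np.mean([0.6, -0.4, 0.6, 0.6, -0.4]) + (1 - g) * np.mean(
        [0.75, -0.25, 0.75]
    )
    ate = summarize_effect(est.tau_hat).ate
    assert ate == pytest.approx(expected, abs=1e-12)
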