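"""Effect-size aggregation, sign conventions, overlap diagnostics and
the sedentary-threshold sweep."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paxlearn import (
    InferenceError,
    PropensityModel,
    apply_sign_convention,
    check_overlap,
    effect_table,
    generate_cohort,
    preprocess,
    run_sedentary_sweep,
    summarize_effect,
)
from paxlearn.synthetic import EffectSpec, SimulationConfig, recovery_config


class TestSummarize:
    def test_three_value_hand_example_with_t_critical_4_3027(self):
        s = summarize_effect(np.array([0.1, 0.2, 0.3]))
        assert s.ate == pytest.approx(0.2, abs=1e-12)
        assert s.se == pytest.approx(0.1 / np.sqrt(3), abs=1e-9)
        assert s.ci_lower == pytest.approx(-0.0484, abs=1e-4)
        assert s.ci_upper == pytest.approx(0.4484, abs=1e-4)
        assert not s.significant

    def test_degenerate_spread_collapses_the_interval(self):
        s = summarize_effect(np.full(10, 0.05))
        assert (s.se, s.ci_lower, s.ci_upper) == (0.0, 0.05, 0.05)
        assert s.p_value == 0.0 and s.significant
        z = summarize_effect(np.zeros(10))
        assert z.p_value == 1.0 and not z.significant

    def test_symmetric_estimates_give_zero_effect_and_p_one(self):
        s = summarize_effect(np.array([-0.2, -0.1, 0.1, 0.2]))
        assert s.ate == pytest.approx(0.0, abs=1e-15)
        assert s.p_value == pytest.approx(1.0)

    def test_fewer_than_two_estimates_is_an_error(self):
        with pytest.raises(InferenceError):
            summarize_effect(np.array([0.1]))

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-0.5, 0.5), min_size=3, max_size=40))
    def test_summary_is_permutation_invariant(self, values):
        tau = np.asarray(values)
        rng = np.random.default_rng(0)
        a = summarize_effect(tau)
        b = summarize_effect(rng.permutation(tau))
        assert a.ate == pytest.approx(b.ate, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_interval_always_brackets_the_estimate(self):
        s = summarize_effect(np.array([0.0, 0.4, -0.3, 0.2]))
        assert s.ci_lower <= s.ate <= s.ci_upper

    def test_ci_width_scales_as_inverse_root_n(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0.1, 0.2, size=2000)
        w1 = np.diff(
            [summarize_effect(base).ci_lower, summarize_effect(base).ci_upper]
        )[0]
        big = np.tile(base, 4)
        w4 = np.diff(
            [summarize_effect(big).ci_lower, summarize_effect(big).ci_upper]
        )[0]
        assert 1.9 <= w1 / w4 <= 2.1


class TestSignConvention:
    def test_negative_raw_risk_difference_reports_as_a_reduction(self):
        raw = summarize_effect(np.full(100, -0.246) + np.linspace(-1e-3, 1e-3, 100))
        rep = apply_sign_convention(raw)
        assert rep.ate == pytest.approx(0.246, abs=1e-6)
        assert rep.ci_lower <= rep.ate <= rep.ci_upper
        assert rep.sign_convention == "reduction"

    def test_zero_effect_is_zero_under_either_convention(self):
        raw = summarize_effect(np.array([-0.1, 0.1, -0.2, 0.2]))
        assert apply_sign_convention(raw).ate == pytest.approx(0.0, abs=1e-15)

    def test_applying_the_convention_twice_is_idempotent(self):
        raw = summarize_effect(np.array([0.1, -0.3, 0.2]))
        once = apply_sign_convention(raw)
        assert apply_sign_convention(once) == once


class TestOverlap:
    def test_randomised_half_assignment_has_full_overlap(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 3))
        t = (rng.random(2000) < 0.5).astype(int)
        from paxlearn import fit_propensity

        rep = check_overlap(fit_propensity(X, t), X, t)
        assert rep.share_outside == 0.0
        assert not rep.warn

    def test_extreme_confounding_raises_the_warning_flag(self):
        cfg = SimulationConfig(
            n_respondents=5000, seed=6,
            treatment_coefficients={"health_perception": 8.0},
            treatment_prevalence=0.7,
        )
        cohort, truth = generate_cohort(cfg)
        processed = preprocess(cohort, min_age=0)
        X = processed.features.to_numpy(float)
        # the construction puts the positive-health stratum above 0.95
        assert (truth.g > 0.95).mean() > 0.10
        from paxlearn import fit_propensity

        rep = check_overlap(fit_propensity(X, truth.treated), X, truth.treated)
        assert rep.warn

    def test_all_clipped_propensities_are_all_outside(self):
        g = PropensityModel(None, constant=0.99)
        rep = check_overlap(g, np.zeros((50, 1)), np.ones(50, dtype=int))
        assert rep.share_outside == 1.0 and rep.warn


@pytest.fixture(scope="module")
def sweep_inputs():
    cohort, _ = generate_cohort(SimulationConfig(n_respondents=4000, seed=12))
    return preprocess(cohort, min_age=60)


class TestSedentarySweep:

    def test_five_thresholds_give_five_rows_per_outcome(self, sweep_inputs):
        p = sweep_inputs
        all_rows = []
        for outcome in p.outcomes.columns:
            res = run_sedentary_sweep(
                p.features, p.outcomes[outcome], p.data, outcome=outcome, seed=0
            )
            assert len(res) == 5
            all_rows.extend(res)
        table = effect_table(all_rows, by_threshold=True)
        assert len(table) == 15
        assert "Sedentary Hours" in table.columns

    def test_threshold_below_the_observed_minimum_is_flagged_not_fatal(
        self, sweep_inputs
    ):
        p = sweep_inputs
        res = run_sedentary_sweep(
            p.features, p.outcomes["depression"], p.data,
            thresholds=(0.0001, 8), outcome="depression", seed=0,
        )
        assert isinstance(res[0], dict) and "error" in res[0]
        assert not isinstance(res[1], dict)

    def test_effect_localised_above_10h_peaks_at_high_thresholds(self):
        wins = 0
        for seed in range(10):
            cfg = recovery_config(0.15, seed=seed, n=4000)
            cfg.causal_treatment = "sedentary_threshold"
            cfg.causal_threshold_hours = 10.0
            cfg.treatment_coefficients = {}
            cohort, _ = generate_cohort(cfg)
            p = preprocess(cohort, min_age=0)
            res = run_sedentary_sweep(
                p.features, p.outcomes["depression"], p.data,
                outcome="depression", seed=seed,
            )
            ate = {4: abs(res[0].ate), 6: abs(res[1].ate),
                   10: abs(res[3].ate), 12: abs(res[4].ate)}
            if min(ate[10], ate[12]) > max(ate[4], ate[6]):
                wins += 1
        assert wins >= 6


def test_report_table_uses_the_published_column_layout():
    s = apply_sign_convention(summarize_effect(
        np.array([-0.2, -0.25, -0.3]), outcome="depression", treatment="high_pa"
    ))
    table = effect_table([s])
    assert list(table.columns) == [
        "Mental Health Indicators", "ATE", "Lower Bound (95% CI)",
        "Upper Bound (95% CI)", "p-Value", "Significant",
    ]
    assert table.loc[0, "Mental Health Indicators"] == "Depression"
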