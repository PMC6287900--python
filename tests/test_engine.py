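"""Markov engine: transition arithmetic, rewards, traces, oracle parity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncms_cea.engine import (
    Arm,
    Conventions,
    adjusted_incidence,
    adjusted_mortality,
    cost_decomposition,
    export_trace,
    labor_gain,
    run_arm,
    run_both_arms,
    run_cohort,
)
from ncms_cea.params import with_values

from conftest import degenerate_except, make_mini_params, matrix_power_trace


class TestAdjustedMortality:
    @pytest.mark.parametrize(
        "q,effect,expected",
        [
            (0.005, -0.10, 0.0049),  # male 20-44 base effect
            (0.0005, -1.0, 0.0),     # clamped at zero
            (0.9, 200.0, 1.0),       # clamped at one
        ],
    )
    def test_additive_per_1000_with_clamp(self, q, effect, expected):
        assert adjusted_mortality(q, effect) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(0, 1))
    @settings(derandomize=True, max_examples=30)
    def test_zero_effect_is_identity(self, q):
        assert adjusted_mortality(q, 0.0) == q

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError):
            adjusted_mortality(1.2, 0.0)


class TestAdjustedIncidence:
    @pytest.mark.parametrize(
        "p,rr,arm,expected",
        [
            (0.10, 0.98, Arm.NCMS, 0.098),
            (0.10, 0.98, Arm.CONTROL, 0.10),
            (0.9, 1.5, Arm.NCMS, 1.0),
        ],
    )
    def test_rr_applies_to_intervention_arm_only(self, p, rr, arm, expected):
        assert adjusted_incidence(p, rr, arm) == pytest.approx(expected)


class TestCostDecomposition:
    @pytest.mark.parametrize(
        "he1,g,rounded", [(359, 0.61, 136), (977, 0.61, 370), (243, 0.61, 92)]
    )
    def test_published_expenditure_increments(self, he1, g, rounded):
        assert round(cost_decomposition(he1, g)) == rounded

    @given(st.floats(1, 1e5))
    @settings(derandomize=True, max_examples=30)
    def test_zero_growth_means_zero_increment(self, he1):
        assert cost_decomposition(he1, 0.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cost_decomposition(0.0, 0.61)
        with pytest.raises(ValueError):
            cost_decomposition(359, -1.0)


class TestLaborGain:
    def test_band_monetization(self, base_params):
        lab = base_params.labor
        assert labor_gain(25, lab) == 0.0
        assert labor_gain(35, lab) == pytest.approx(0.13 * 1029 + 1.10 * 1.44)  # 135.354
        assert labor_gain(55, lab) == pytest.approx(0.07 * 1029 + 1.28 * 1.44)  # 73.8732

    def test_band_edges(self, base_params):
        lab = base_params.labor
        assert labor_gain(29, lab) == 0.0
        assert labor_gain(30, lab) == labor_gain(49, lab)
        assert labor_gain(50, lab) != labor_gain(49, lab)


class TestRunCohortAnnuities:
    """With no deaths and no onset, QALYs reduce to a discounted annuity."""

    def test_undiscounted_annuity(self):
        p = make_mini_params(n_cycles=80, q=0.0, incidence=0.0, u_n=1.0, u_h=1.0,
                             extra_he=0.0, htn_cost=0.0, r=0.0)
        _, out = run_cohort(p, Arm.CONTROL, "male")
        assert out.qalys == pytest.approx(80.0, abs=1e-9)

    def test_discounted_annuity_closed_form(self):
        p = make_mini_params(n_cycles=80, q=0.0, incidence=0.0, u_n=1.0, u_h=1.0,
                             extra_he=0.0, htn_cost=0.0, r=0.03)
        _, out = run_cohort(p, Arm.CONTROL, "male")
        v = 1.0 / 1.03
        expected = (1 - v**80) / (1 - v)  # geometric sum over t = 0..79
        assert out.qalys == pytest.approx(expected, rel=1e-12)


class TestMatrixOracle:
    """Engine occupancies match explicit transition-matrix products."""

    @pytest.mark.parametrize("arm", list(Arm))
    @pytest.mark.parametrize("n_cycles", [1, 3, 5])
    def test_miniature_models(self, arm, n_cycles):
        p = make_mini_params(n_cycles=n_cycles, q=0.1, incidence=0.2, u_n=1.0, u_h=0.9,
                             extra_he=100.0, htn_cost=50.0, r=0.0,
                             rr=0.9, mortality_effect=-5.0)
        trace, out = run_cohort(p, arm, "male")
        expected = matrix_power_trace(p, arm, "male")
        got = np.column_stack([trace.occ_normotensive, trace.occ_hypertensive, trace.occ_dead])
        np.testing.assert_allclose(got, expected, atol=1e-12)
        # rewards recomputed by hand from the oracle occupancies
        q_exp = sum(expected[t, 0] * 1.0 + expected[t, 1] * 0.9 for t in range(n_cycles))
        assert out.qalys == pytest.approx(q_exp, abs=1e-12)
        htn = sum(expected[t, 1] * 50.0 for t in range(n_cycles))
        assert out.cost_components["htn_medical"] == pytest.approx(htn, abs=1e-12)
        if arm is Arm.CONTROL:
            assert out.cost_components["extra_health_expenditure"] == 0.0
        else:
            alive = expected[:, 0] + expected[:, 1]
            assert out.cost_components["extra_health_expenditure"] == pytest.approx(
                100.0 * alive.sum(), abs=1e-10
            )

    def test_three_cycle_hand_values(self):
        """The 3-cycle miniature agrees with hand matrix multiplication."""
        p = make_mini_params()
        trace, _ = run_cohort(p, Arm.CONTROL, "male")
        # cycle 1: alive 0.9, of which 20% converted
        assert trace.occ_normotensive[1] == pytest.approx(0.9 * 0.8, abs=1e-15)
        assert trace.occ_hypertensive[1] == pytest.approx(0.9 * 0.2, abs=1e-15)
        # cycle 2
        assert trace.occ_normotensive[2] == pytest.approx(0.9 * 0.8 * 0.9 * 0.8, abs=1e-15)
        assert trace.occ_hypertensive[2] == pytest.approx(0.9 * 0.2 * 0.9 + 0.9 * 0.8 * 0.9 * 0.2, abs=1e-15)


class TestTraceInvariants:
    def test_conservation_and_monotone_death(self, base_params):
        for arm in Arm:
            for sex in ("male", "female"):
                trace, _ = run_cohort(base_params, arm, sex)
                total = trace.occ_normotensive + trace.occ_hypertensive + trace.occ_dead
                np.testing.assert_allclose(total, 1.0, atol=1e-12)
                assert np.all(np.diff(trace.occ_dead) > 0)  # positive mortality everywhere
                assert np.all(trace.occ_normotensive >= 0)
                assert np.all(trace.occ_hypertensive >= 0)

    def test_everyone_exits_by_terminal_age(self, base_params):
        trace, _ = run_cohort(base_params, Arm.CONTROL, "male")
        assert len(trace.ages) == 80 and trace.ages[-1] == 99


class TestDirectionalProperties:
    def test_discounting_monotonicity(self, base_params):
        outs = []
        for r in (0.0, 0.03, 0.05):
            q = with_values(base_params, {"discount_rate": r})
            outs.append(run_arm(q, Arm.CONTROL))
        assert outs[0].qalys > outs[1].qalys > outs[2].qalys
        assert outs[0].cost_total > outs[1].cost_total > outs[2].cost_total

    def test_beneficial_effects_raise_intervention_qalys(self, base_params):
        p = with_values(
            base_params,
            {"mortality_effect.male.60+": -0.5, "mortality_effect.female.60+": -0.5},
        )
        outs = run_both_arms(p)
        assert outs[Arm.NCMS].qalys >= outs[Arm.CONTROL].qalys

    def test_currency_scale_equivariance(self, base_params):
        k = 3.7
        scaled = with_values(
            base_params,
            {
                "total_health_expenditure": base_params.costs.he1.base * k,
                "htn_annual_cost": base_params.costs.htn_annual_cost.base * k,
                "annual_wage": base_params.labor.annual_wage.base * k,
                "agri_hourly": base_params.labor.agri_hourly.base * k,
            },
        )
        for arm in Arm:
            o0 = run_arm(base_params, arm)
            o1 = run_arm(scaled, arm)
            assert o1.cost_total == pytest.approx(k * o0.cost_total, rel=1e-12)
            assert o1.qalys == pytest.approx(o0.qalys, rel=1e-14)

    def test_labor_benefit_is_nonpositive_offset(self, base_params):
        out = run_arm(base_params, Arm.NCMS)
        assert out.cost_components["labor_benefit"] < 0
        assert out.cost_total == pytest.approx(sum(out.cost_components.values()))


class TestConventions:
    def test_discount_offset_scales_both_arms_equally(self, base_params):
        plain = run_both_arms(base_params)
        shifted = run_both_arms(base_params, Conventions(discount_age_offset=20))
        k = 1.03 ** -20
        for arm in Arm:
            assert shifted[arm].cost_total == pytest.approx(k * plain[arm].cost_total, rel=1e-9)
            assert shifted[arm].qalys == pytest.approx(k * plain[arm].qalys, rel=1e-9)

    def test_half_cycle_shrinks_rewards_with_mortality(self, base_params):
        plain = run_arm(base_params, Arm.CONTROL)
        hc = run_arm(base_params, Arm.CONTROL, Conventions(half_cycle=True))
        assert hc.qalys < plain.qalys  # occupancies only decline within a cycle


class TestExportTrace:
    def test_columns_and_totals(self, base_params):
        df = export_trace(base_params, Arm.NCMS, "female")
        assert list(df.columns[:5]) == ["cycle", "age", "occ_normotensive", "occ_hypertensive", "occ_dead"]
        _, out = run_cohort(base_params, Arm.NCMS, "female")
        assert df["qaly_disc"].sum() == pytest.approx(out.qalys, rel=1e-12)
        assert df["cost_disc_total"].sum() == pytest.approx(out.cost_total, rel=1e-12)
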