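"""Unit and property tests for the deterministic cohort model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emic
from emic.errors import (
    ConfigurationError,
    InputDomainError,
    UnsupportedFeatureError,
)

from conftest import constant_hazard, flat_series


def flat_lifetable(q=0.01, max_age=105, base_year=2011):
    return emic.LifeTable(pd.Series(q, index=range(max_age + 1)),
                          base_year=base_year)


class TestTrendProjection:
    def test_no_trend_is_identity(self):
        qt = emic.project_cohort_hazard(flat_lifetable(), None, 0)
        assert (qt == 0.01).all()
        assert list(qt.index) == list(range(0, 106))

    def test_two_elapsed_years_at_two_percent(self):
        # age 2 reached in 2013 from a 2011 baseline: two years of 2 % decline
        qt = emic.project_cohort_hazard(flat_lifetable(), emic.nz_default_trend(), 0)
        assert qt.loc[2] == pytest.approx(0.01 * 0.98**2, rel=1e-14)

    def test_trend_switches_after_2026(self):
        """Age 20 reached in 2031: 15 years at 2 %, then 5 at 1 %.

        Oracle: an explicit year-by-year loop of multiplications.
        """
        expected = 0.01
        for year in range(2012, 2032):
            expected *= (1 - 0.02) if year <= 2026 else (1 - 0.01)
        qt = emic.project_cohort_hazard(flat_lifetable(), emic.nz_default_trend(), 0)
        assert qt.loc[20] == pytest.approx(expected, rel=1e-14)
        assert qt.loc[20] == pytest.approx(0.0070237, abs=1e-7)

    def test_trend_relative_to_start_age(self):
        # a 60-year-old reaches age 62 after the same two elapsed years
        qt = emic.project_cohort_hazard(flat_lifetable(), emic.nz_default_trend(), 60)
        assert qt.index[0] == 60
        assert qt.loc[60] == 0.01  # baseline year untouched
        assert qt.loc[62] == pytest.approx(0.01 * 0.98**2, rel=1e-14)

    def test_start_age_outside_table(self):
        with pytest.raises(InputDomainError):
            emic.project_cohort_hazard(flat_lifetable(max_age=50), None, 60)

    def test_base_year_mismatch(self):
        with pytest.raises(ConfigurationError):
            emic.project_cohort_hazard(
                flat_lifetable(base_year=2015), emic.nz_default_trend(2011), 0)

    def test_projected_probabilities_stay_in_unit_interval(self):
        lt = emic.LifeTable(pd.Series(1.0, index=range(0, 106)), base_year=2011)
        qt = emic.project_cohort_hazard(lt, emic.nz_default_trend(), 0)
        assert ((qt >= 0) & (qt <= 1)).all()

    def test_trend_spec_validation(self):
        with pytest.raises(ConfigurationError):
            emic.MortalityTrendSpec(2011, (emic.TrendSegment(0.02, 2026),))
        with pytest.raises(InputDomainError):
            emic.MortalityTrendSpec(2011, (emic.TrendSegment(1.0, None),))


class TestSurvivalCurve:
    def test_zero_hazard(self):
        s = emic.survival_curve(constant_hazard(0.0, 10), 0)
        assert (s == 1.0).all()

    def test_certain_immediate_death(self):
        s = emic.survival_curve(constant_hazard(1.0, 3), 0)
        assert s.tolist() == [1.0, 0.0, 0.0]

    def test_geometric_decay(self):
        s = emic.survival_curve(constant_hazard(0.1, 3), 0)
        assert s.tolist() == pytest.approx([1.0, 0.9, 0.81])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=60)
    def test_monotone_and_bounded(self, qs):
        s = emic.survival_curve(
            pd.Series(qs, index=range(len(qs))), 0).to_numpy()
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 0)
        assert np.all((s >= 0) & (s <= 1))


class TestDiscountedStreams:
    def test_haly_undiscounted_fixed_lifespan(self):
        # no morbidity, no discounting, death after exactly 10 lived years
        q = constant_hazard(0.0, 10)
        s = emic.survival_curve(q, 0)
        morb = emic.MorbiditySchedule(flat_series(0.0, 10))
        assert emic.discounted_haly(s, morb, 0.0, 0) == 10.0

    def test_haly_single_year_discounted(self):
        # half-health year, certain death after it: 0.5 / 1.03
        s = emic.survival_curve(constant_hazard(1.0, 1), 0)
        morb = emic.MorbiditySchedule(flat_series(0.5, 1))
        assert emic.discounted_haly(s, morb, 0.03, 0) == pytest.approx(
            0.485437, abs=5e-7)

    def test_haly_constant_hazard_closed_form(self):
        # geometric series: sum (1-q)^(n-1) (1-pi) / (1+r)^n = (1-pi)/(q+r)
        q, pi, r = 0.2, 0.1, 0.03
        n = 2000
        s = emic.survival_curve(constant_hazard(q, n), 0)
        morb = emic.MorbiditySchedule(flat_series(pi, n))
        assert emic.discounted_haly(s, morb, r, 0) == pytest.approx(
            (1 - pi) / (q + r), rel=1e-9)

    def test_cost_zero(self):
        s = emic.survival_curve(constant_hazard(0.0, 5), 0)
        costs = emic.CostSchedule(flat_series(0.0, 5), adjusted=True,
                                  expected=flat_series(0.0, 5))
        assert emic.discounted_cost(s, costs, 0.0, 0) == 0.0

    def test_cost_undiscounted_fixed_lifespan(self):
        s = emic.survival_curve(constant_hazard(0.0, 3), 0)
        costs = emic.CostSchedule(flat_series(100.0, 3), adjusted=True,
                                  expected=flat_series(100.0, 3))
        assert emic.discounted_cost(s, costs, 0.0, 0) == 300.0

    def test_cost_constant_hazard_closed_form(self):
        q, c, r = 0.2, 1000.0, 0.03
        n = 2000
        s = emic.survival_curve(constant_hazard(q, n), 0)
        costs = emic.CostSchedule(flat_series(c, n), adjusted=True,
                                  expected=flat_series(c, n))
        assert emic.discounted_cost(s, costs, r, 0) == pytest.approx(
            c / (q + r), rel=1e-9)

    def test_unadjusted_costs_rejected_unless_opted_out(self):
        s = emic.survival_curve(constant_hazard(0.1, 5), 0)
        costs = emic.CostSchedule(flat_series(100.0, 5))
        with pytest.raises(ConfigurationError):
            emic.discounted_cost(s, costs, 0.03, 0)
        assert emic.discounted_cost(s, costs, 0.0, 0,
                                    allow_unadjusted=True) > 0

    def test_invalid_schedules_rejected(self):
        with pytest.raises(InputDomainError):
            emic.MorbiditySchedule(flat_series(1.0, 5))
        with pytest.raises(InputDomainError):
            emic.CostSchedule(flat_series(-1.0, 5))

    @pytest.mark.parametrize("r_lo,r_hi", [(0.0, 0.03), (0.03, 0.06)])
    def test_streams_strictly_decrease_in_discount_rate(
            self, synthetic_inputs, r_lo, r_hi):
        lt, morb, costs = synthetic_inputs
        lo = emic.run_cohort(lt, morb, costs, emic.ScenarioSpec(r=r_lo), 30)
        hi = emic.run_cohort(lt, morb, costs, emic.ScenarioSpec(r=r_hi), 30)
        assert hi.haly < lo.haly
        assert hi.cost < lo.cost

    def test_hale_equals_le_without_morbidity_or_discounting(self, params):
        lt = emic.gompertz_lifetable(params)
        n = 106
        morb = emic.MorbiditySchedule(flat_series(0.0, n))
        s = emic.survival_curve(
            emic.project_cohort_hazard(lt, None, 0), 0)
        assert emic.discounted_haly(s, morb, 0.0, 0) == pytest.approx(
            emic.life_expectancy(s), rel=1e-14)


class TestAdjustCosts:
    def test_identity_when_unscaled(self):
        hz = constant_hazard(0.01, 10)
        raw = emic.CostSchedule(flat_series(500.0, 10),
                                lyol=flat_series(0.0, 10))
        adj = emic.adjust_costs(raw, hz, global_scale=1.0)
        assert adj.adjusted
        assert adj.expected.tolist() == pytest.approx([500.0] * 10)

    def test_midlife_no_band_multiplier(self):
        # age 50: outside the decedent-cost bands, m = 1
        hz = pd.Series([0.005], index=[50])
        raw = emic.CostSchedule(pd.Series([1000.0], index=[50]),
                                lyol=pd.Series([20000.0], index=[50]))
        adj = emic.adjust_costs(raw, hz)
        assert adj.expected.loc[50] == pytest.approx(
            1.2 * (1000 + 0.005 * 20000))  # = 1320

    def test_old_age_band_multiplier(self):
        # age 80 sits in the 75-84 band with multiplier 1.2
        hz = pd.Series([0.05], index=[80])
        raw = emic.CostSchedule(pd.Series([1000.0], index=[80]),
                                lyol=pd.Series([20000.0], index=[80]))
        adj = emic.adjust_costs(raw, hz)
        assert adj.expected.loc[80] == pytest.approx(
            1.2 * (1000 + 1.2 * 0.05 * 20000))  # = 2640

    def test_band_edges(self):
        hz = pd.Series(0.1, index=range(60, 106))
        raw = emic.CostSchedule(flat_series(0.0, 46, start=60),
                                lyol=flat_series(1000.0, 46, start=60))
        adj = emic.adjust_costs(raw, hz, global_scale=1.0)
        exp = adj.expected
        assert exp.loc[64] == pytest.approx(0.1 * 1000)
        assert exp.loc[65] == pytest.approx(1.1 * 0.1 * 1000)
        assert exp.loc[74] == pytest.approx(1.1 * 0.1 * 1000)
        assert exp.loc[75] == pytest.approx(1.2 * 0.1 * 1000)
        assert exp.loc[84] == pytest.approx(1.2 * 0.1 * 1000)
        assert exp.loc[85] == pytest.approx(1.3 * 0.1 * 1000)
        assert exp.loc[100] == pytest.approx(1.3 * 0.1 * 1000)

    def test_multipliers_without_decedent_costs(self):
        hz = constant_hazard(0.01, 10)
        raw = emic.CostSchedule(flat_series(500.0, 10))
        with pytest.raises(ConfigurationError):
            emic.adjust_costs(raw, hz, lyol_multipliers=((65, None, 1.1),))
        # without multipliers the background-only schedule just scales
        adj = emic.adjust_costs(raw, hz)
        assert adj.expected.tolist() == pytest.approx([600.0] * 10)


class TestLifeExpectancy:
    def test_certain_death_after_one_year(self):
        s = emic.survival_curve(constant_hazard(1.0, 1), 0)
        assert emic.life_expectancy(s) == 1.0

    def test_constant_half_hazard(self):
        s = emic.survival_curve(constant_hazard(0.5, 200), 0)
        assert emic.life_expectancy(s) == pytest.approx(2.0, rel=1e-9)

    def test_truncation(self):
        s = emic.survival_curve(constant_hazard(0.0, 10), 0)
        assert emic.life_expectancy(s) == 10.0


class TestEmicAlgebra:
    def test_worked_example(self):
        assert emic.emic_ideal(26.2, 51_000, 45_000) == pytest.approx(
            1_128_000, abs=1e-6)

    def test_break_even(self):
        assert emic.emic_ideal(10.0, 250_000, 25_000) == 0.0

    def test_high_threshold_row(self):
        assert emic.emic_ideal(28.8, 42_000, 100_000) == pytest.approx(
            2_838_000, abs=1e-6)

    def test_negative_reported_not_clamped(self):
        assert emic.emic_ideal(1.0, 100_000, 45_000) == -55_000

    def test_domain(self):
        with pytest.raises(InputDomainError):
            emic.emic_ideal(-1.0, 0.0, 45_000)

    @given(h=st.floats(0, 120), c=st.floats(0, 5e5),
           cet1=st.floats(0, 2e5), cet2=st.floats(0, 2e5))
    @settings(derandomize=True, max_examples=100)
    def test_affine_in_threshold(self, h, c, cet1, cet2):
        d = emic.emic_ideal(h, c, cet2) - emic.emic_ideal(h, c, cet1)
        assert d == pytest.approx(h * (cet2 - cet1), rel=1e-9, abs=1e-4)

    def test_general_reduces_to_ideal(self):
        assert emic.emic_general(26.2, 51_000, 45_000, 1.0, 1.0) == \
            emic.emic_ideal(26.2, 51_000, 45_000)

    def test_general_scales_linearly(self):
        assert emic.emic_general(26.2, 51_000, 45_000, 0.5, 0.8) == \
            pytest.approx(0.4 * 1_128_000, abs=1e-6)

    def test_general_zero_risk(self):
        assert emic.emic_general(26.2, 51_000, 45_000, 0.0, 1.0) == 0.0

    def test_multi_year_risk_unsupported(self):
        with pytest.raises(UnsupportedFeatureError):
            emic.emic_general(26.2, 51_000, 45_000, 1.0, 1.0, risk_duration=2)

    def test_scenario_validation(self):
        with pytest.raises(InputDomainError):
            emic.ScenarioSpec(p=1.5)
        with pytest.raises(InputDomainError):
            emic.ScenarioSpec(r=-0.01)


class TestRunCohort:
    def test_matches_manual_composition(self, synthetic_inputs):
        lt, morb, costs = synthetic_inputs
        scn = emic.ScenarioSpec(trend=emic.nz_default_trend())
        res = emic.run_cohort(lt, morb, costs, scn, 17)
        hz = emic.project_cohort_hazard(lt, scn.trend, 17, max_age=scn.max_age)
        s = emic.survival_curve(hz, 17)
        adj = emic.adjust_costs(costs, hz)
        assert res.haly == emic.discounted_haly(s, morb, scn.r, 17)
        assert res.cost == emic.discounted_cost(s, adj, scn.r, 17)
        assert res.emic == emic.emic_ideal(res.haly, res.cost, scn.cet)
        assert res.le == emic.life_expectancy(s)
        assert not res.cost_ineffective

    def test_survival_invariants(self, synthetic_inputs):
        lt, morb, costs = synthetic_inputs
        res = emic.run_cohort(lt, morb, costs, emic.ScenarioSpec(), 0)
        s = res.survival.to_numpy()
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 0)
        assert res.haly <= res.le
        assert res.cost >= 0
        assert res.survival.index[-1] == 105
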