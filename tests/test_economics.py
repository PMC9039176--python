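"""Discounting, cost accrual, human-capital losses and QALY valuation."""

import numpy as np
import pytest

import rtburden as rb
from rtburden.economics import (
    cost_breakdown,
    cost_streams,
    cv_event_utility,
    direct_costs,
    discount_factor,
    indirect_costs,
    qalys,
)
from rtburden.markov import CohortTrace, run_cohort
from rtburden.parameters import ValidationError
from rtburden.risk import build_cycle_matrices


def event_trace(event_cycle: int, horizon: int, kind: str = "nonfatal") -> CohortTrace:
    """A unit cohort experiencing one event at a given cycle, no other exits."""
    occupancy = np.zeros((horizon + 1, 6))
    state_after = 3 if kind == "nonfatal" else 4
    for t in range(horizon + 1):
        occupancy[t, 2 if t < event_cycle else state_after] = 1.0
    new_nonfatal = np.zeros(horizon + 1)
    new_fatal_direct = np.zeros(horizon + 1)
    if kind == "nonfatal":
        new_nonfatal[event_cycle] = 1.0
    else:
        new_fatal_direct[event_cycle] = 1.0
    return CohortTrace(occupancy, new_nonfatal, new_fatal_direct, np.zeros(horizon + 1))


def quiet_trace(horizon: int) -> CohortTrace:
    occupancy = np.zeros((horizon + 1, 6))
    occupancy[:, 2] = 1.0
    zero = np.zeros(horizon + 1)
    return CohortTrace(occupancy, zero, zero.copy(), zero.copy())


class TestDiscounting:
    @pytest.mark.parametrize(
        "rate,t,expected", [(0.03, 0, 1.0), (0.03, 1, 0.970874), (0.0, 7, 1.0)]
    )
    def test_worked_values(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, abs=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(-0.01, 1)


class TestEventUtility:
    def test_published_value(self):
        assert round(cv_event_utility(0.77, 0.11, 0.91), 4) == 0.6769

    def test_no_disutility_is_identity(self):
        assert cv_event_utility(0.77, 0.0, 0.91) == 0.77

    def test_proportional_decrement(self):
        assert cv_event_utility(1.0, 0.11, 0.91) == pytest.approx(0.87912, abs=1e-5)

    def test_bounds_enforced(self):
        with pytest.raises(ValidationError):
            cv_event_utility(0.77, 0.95, 0.91)
        with pytest.raises(ValidationError):
            cv_event_utility(0.77, 0.1, 1.5)


class TestDirectCosts:
    def test_zero_event_trace_costs_nothing(self, ps):
        costs = direct_costs(quiet_trace(20), ps)
        assert all(value == 0.0 for value in costs.values())

    def test_first_year_bundle(self, ps):
        """One woman entering the non-fatal state in cycle 1, undiscounted."""
        bundle = 455.62 + 4547.51 + 149.0882 + 54.12 + 196.33
        costs = direct_costs(event_trace(1, 1), ps)
        assert sum(costs.values()) == pytest.approx(bundle, abs=1e-9)
        assert bundle == pytest.approx(5402.6682, abs=1e-9)

    def test_discounting_composes(self, ps):
        costs = direct_costs(event_trace(2, 2), ps)
        assert sum(costs.values()) == pytest.approx(
            5402.6682 * discount_factor(0.03, 1), abs=1e-6
        )

    def test_subsequent_years_accrue_followup_and_pharma(self, ps):
        undiscounted = direct_costs(event_trace(1, 2), ps, discounted=False)
        later = 94.71 + 155.78 + 149.0882
        assert sum(undiscounted.values()) == pytest.approx(5402.6682 + later, abs=1e-9)

    def test_direct_fatal_event_incurs_only_ae(self, ps):
        costs = direct_costs(event_trace(1, 1, kind="fatal"), ps)
        assert costs["ae"] == pytest.approx(455.62)
        assert sum(costs.values()) == pytest.approx(455.62)


class TestIndirectCosts:
    def test_retired_cohort_costs_nothing(self, ps):
        costs = indirect_costs(event_trace(1, 5), ps, age_at_start=65)
        assert all(value == 0.0 for value in costs.values())

    def test_first_year_sick_leave(self, ps):
        costs = indirect_costs(event_trace(1, 1), ps, age_at_start=45)
        expected = 0.6490 * 0.9616 * 48 * 252.30
        assert costs["temporary_sick_leave"] == pytest.approx(expected, abs=1e-9)

    def test_fatal_event_at_64_loses_exactly_one_wage_year(self, ps):
        costs = indirect_costs(event_trace(1, 1, kind="fatal"), ps, age_at_start=64)
        assert costs["premature_death"] == pytest.approx(0.6490 * 55559.75, abs=1e-6)

    def test_permanent_disability_annuity_runs_to_retirement(self, ps):
        undiscounted_ps = ps.replace(discount_costs=0.0)
        costs = indirect_costs(event_trace(1, 1), undiscounted_ps, age_at_start=60)
        expected = 0.6490 * 0.0394 * 55559.75 * 5  # five years to retirement
        assert costs["permanent_disability"] == pytest.approx(expected, rel=1e-12)


class TestQalys:
    def test_single_undiscounted_cycle_in_initial_state(self, ps):
        outcome = qalys(quiet_trace(1), ps.replace(discount_outcomes=0.0))
        assert outcome.qalys == pytest.approx(0.77)
        assert outcome.life_years == pytest.approx(1.0)

    def test_all_dead_scores_zero(self, ps):
        occupancy = np.zeros((3, 6))
        occupancy[:, 4] = 1.0
        zero = np.zeros(3)
        trace = CohortTrace(occupancy, zero, zero.copy(), zero.copy())
        assert qalys(trace, ps).qalys == 0.0

    def test_full_health_no_discounting_scores_horizon(self, ps):
        full = ps.replace(u_initial=1.0, disutility_ref=0.0, discount_outcomes=0.0)
        assert qalys(quiet_trace(20), full).qalys == pytest.approx(20.0)

    def test_discounting_strictly_reduces(self, ps):
        trace = quiet_trace(20)
        assert qalys(trace, ps).qalys < qalys(trace, ps, discounted=False).qalys

    def test_higher_event_risk_never_raises_qalys(self, ps, tables):
        matrices = build_cycle_matrices(60, ps, tables.fatal_cv, tables.background, False)
        bumped = matrices.copy()
        for t in range(bumped.shape[0]):
            for row in range(3):
                bumped[t, row, 4] += 0.005
                bumped[t, row, row] -= 0.005
        base = qalys(run_cohort("high", matrices), ps)
        worse = qalys(run_cohort("high", bumped), ps)
        assert worse.qalys < base.qalys


class TestBreakdown:
    def test_total_is_direct_plus_indirect(self, ps, tables):
        matrices = build_cycle_matrices(55, ps, tables.fatal_cv, tables.background, True)
        breakdown = cost_breakdown(run_cohort("high", matrices), ps, age_at_start=55)
        assert breakdown.total == pytest.approx(
            breakdown.direct_total + breakdown.indirect_total, abs=1e-9
        )
        assert breakdown.direct_total > 0 and breakdown.indirect_total > 0

    def test_stream_export_matches_aggregates(self, ps, tables):
        matrices = build_cycle_matrices(55, ps, tables.fatal_cv, tables.background, True)
        trace = run_cohort("high", matrices)
        streams = cost_streams(trace, ps, age_at_start=55)
        assert set(streams.columns) == {"cycle", "category", "undiscounted", "discounted"}
        breakdown = cost_breakdown(trace, ps, age_at_start=55)
        assert streams["discounted"].sum() == pytest.approx(breakdown.total, abs=1e-9)
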