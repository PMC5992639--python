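"""Cost schedules, discounting and accrual."""

from dataclasses import replace

import numpy as np
import pytest

from vlucea.markov import CohortTrace, run_cohort
from vlucea.outcomes import (
    CATEGORIES,
    accrue,
    build_cost_schedule,
    count_outputs,
    discount_factor,
)
from vlucea.parameters import (
    CostCategory,
    CYCLES_PER_QUARTER,
    HealthState,
    HorizonProbability,
    Payer,
    UnitCosts,
    UtilitySet,
    ValidationError,
    baseline_strategies,
)

USUAL, OPTIMAL = baseline_strategies()


def _single_person_trace(state: HealthState, n_cycles: int = 1) -> CohortTrace:
    occ = np.zeros((n_cycles + 1, 5))
    occ[0, state] = 1.0
    occ[1:, HealthState.DEAD] = 1.0
    z = np.zeros(n_cycles + 1)
    admissions = z.copy()
    incident = z.copy()
    if state == HealthState.HOSPITALISED:
        admissions = z.copy()
        admissions[0] = 1.0
    if state == HealthState.UNHEALED:
        incident[0] = 1.0
    deaths = z.copy()
    deaths[1] = 1.0
    return CohortTrace(
        occupancy=occ,
        entrants_incident=incident,
        entrants_recurrent=z.copy(),
        entrants_discharge=z.copy(),
        admissions=admissions,
        deaths=deaths,
        growth_inflow=z.copy(),
    )


class TestCostSchedule:
    def test_usual_healed_costs_nothing(self, bundle, aggregate):
        sched = build_cost_schedule(
            bundle.unit_costs, USUAL, aggregate, option=1, settings=bundle.settings
        )
        assert sched.recurring_total(HealthState.HEALED) == 0.0
        assert sched.entry_total(HealthState.HEALED) == 0.0

    def test_hospital_entry_cost_payer_split(self, bundle, aggregate):
        sched = build_cost_schedule(
            bundle.unit_costs, USUAL, aggregate, option=1, settings=bundle.settings
        )
        entry = sched.entry[HealthState.HOSPITALISED]
        cat = list(CATEGORIES).index(CostCategory.HOSPITAL)
        payers = [Payer.AUSTRALIAN_GOVT, Payer.STATE_GOVT, Payer.OUT_OF_POCKET]
        values = {p: entry[cat, payers.index(p)] for p in payers}
        assert values[Payer.AUSTRALIAN_GOVT] == pytest.approx(7_332.64)
        assert values[Payer.STATE_GOVT] == pytest.approx(10_998.96)
        assert values[Payer.OUT_OF_POCKET] == 0.0

    def test_optimal_healed_option1_amortised_over_quarter(self, bundle, aggregate):
        sched = build_cost_schedule(
            bundle.unit_costs, OPTIMAL, aggregate, option=1, settings=bundle.settings
        )
        expected = (58.55 + 97.75) / CYCLES_PER_QUARTER
        assert sched.recurring_total(HealthState.HEALED) == pytest.approx(expected)

    def test_optimal_compression_fully_federal(self, bundle, aggregate):
        sched = build_cost_schedule(
            bundle.unit_costs, OPTIMAL, aggregate, option=1, settings=bundle.settings
        )
        comp = list(CATEGORIES).index(CostCategory.COMPRESSION)
        rec = sched.recurring[HealthState.UNHEALED, comp]
        assert rec[0] > 0  # Australian government
        assert rec[1] == rec[2] == 0.0

    def test_option2_cheaper_services_than_option1(self, bundle, aggregate):
        """Provider-mix pricing (community nurses are cheaper than NPs)
        lowers Option-2 unhealed service costs."""
        s1 = build_cost_schedule(
            bundle.unit_costs, OPTIMAL, aggregate, option=1, settings=bundle.settings
        )
        s2 = build_cost_schedule(
            bundle.unit_costs, OPTIMAL, aggregate, option=2, settings=bundle.settings
        )
        svc = list(CATEGORIES).index(CostCategory.SERVICES)
        assert (
            s2.recurring[HealthState.UNHEALED, svc].sum()
            < s1.recurring[HealthState.UNHEALED, svc].sum()
        )

    def test_invalid_option_rejected(self, bundle, aggregate):
        with pytest.raises(ValidationError):
            build_cost_schedule(bundle.unit_costs, USUAL, aggregate, option=3)


class TestDiscountFactor:
    def test_examples(self):
        assert discount_factor(0, 0.05) == 1.0
        assert discount_factor(77, 0.0) == 1.0
        assert discount_factor(130, 0.05) == pytest.approx(1.05**-5)

    def test_vectorised_monotone(self):
        t = np.arange(131)
        d = discount_factor(t, 0.05)
        assert (np.diff(d) < 0).all()


class TestAccrue:
    def test_empty_cohort_zero_cost_and_qalys(self, bundle, aggregate):
        settings = replace(bundle.settings, prevalence_at_cycle0=0.0)
        juris = replace(aggregate, population_60plus=0.0, growth_per_cycle=0.0)
        trace = run_cohort(USUAL, juris, settings)
        sched = build_cost_schedule(bundle.unit_costs, USUAL, juris, 1, settings)
        res = accrue(trace, sched, bundle.utilities, settings)
        assert res.total_cost == 0.0
        assert res.qalys == 0.0

    def test_one_hospitalised_cycle_qaly(self, bundle, aggregate):
        trace = _single_person_trace(HealthState.HOSPITALISED)
        sched = build_cost_schedule(
            bundle.unit_costs, USUAL, aggregate, 1, bundle.settings
        )
        res = accrue(trace, sched, bundle.utilities, bundle.settings)
        assert res.qalys == pytest.approx(0.54 / 26)

    def test_payer_and_category_totals_sum_to_grand_total(self, bundle, aggregate):
        trace = run_cohort(USUAL, aggregate, bundle.settings)
        sched = build_cost_schedule(
            bundle.unit_costs, USUAL, aggregate, 1, bundle.settings
        )
        res = accrue(trace, sched, bundle.utilities, bundle.settings)
        by_payer = sum(res.cost_by_payer(p) for p in Payer)
        by_cat = sum(res.cost_by_category(c) for c in CostCategory)
        assert by_payer == pytest.approx(res.total_cost, abs=1e-6)
        assert by_cat == pytest.approx(res.total_cost, abs=1e-6)
        assert res.total_cost > 0

    def test_discounted_below_undiscounted(self, bundle, aggregate):
        trace = run_cohort(OPTIMAL, aggregate, bundle.settings)
        sched = build_cost_schedule(
            bundle.unit_costs, OPTIMAL, aggregate, 1, bundle.settings
        )
        res = accrue(trace, sched, bundle.utilities, bundle.settings)
        assert res.total_cost < res.cost_undiscounted.sum()
        assert res.qalys < res.qalys_undiscounted

    def test_zero_unit_costs_leave_qalys_unchanged(self, bundle, aggregate):
        trace = run_cohort(USUAL, aggregate, bundle.settings)
        zero_costs = UnitCosts(
            **{k: 0.0 for k in UnitCosts().__dict__ if k != "community_nurse_visit_hours"}
        )
        sched0 = build_cost_schedule(zero_costs, USUAL, aggregate, 1, bundle.settings)
        sched1 = build_cost_schedule(
            bundle.unit_costs, USUAL, aggregate, 1, bundle.settings
        )
        res0 = accrue(trace, sched0, bundle.utilities, bundle.settings)
        res1 = accrue(trace, sched1, bundle.utilities, bundle.settings)
        assert res0.total_cost == 0.0
        assert res0.qalys == res1.qalys

    def test_qaly_upper_bound(self, bundle, aggregate):
        trace = run_cohort(USUAL, aggregate, bundle.settings)
        sched = build_cost_schedule(
            bundle.unit_costs, USUAL, aggregate, 1, bundle.settings
        )
        res = accrue(trace, sched, bundle.utilities, bundle.settings)
        affected_cycles = trace.occupancy[:-1, 1:4].sum()
        assert res.qalys <= affected_cycles * 0.75 / 26 + 1e-9

    def test_unit_utilities_zero_discount_gives_person_years(self, bundle, aggregate):
        settings = replace(bundle.settings, discount_rate_per_year=0.0)
        utilities = UtilitySet(u_healed=1.0, u_unhealed=1.0, hosp_decrement=0.0)
        trace = run_cohort(USUAL, aggregate, settings)
        sched = build_cost_schedule(bundle.unit_costs, USUAL, aggregate, 1, settings)
        res = accrue(trace, sched, utilities, settings)
        person_years = trace.occupancy[:-1, 1:4].sum() / 26
        assert res.qalys == pytest.approx(person_years)


class TestCountOutputs:
    def test_identical_strategies_avoid_nothing(self, bundle, aggregate):
        trace = run_cohort(USUAL, aggregate, bundle.settings)
        out = count_outputs(trace, trace)
        assert out["hospitalisations_avoided"] == 0.0

    def test_equal_hazards_different_healing_still_avoids(self, bundle, aggregate):
        """With equal hospitalisation hazards, faster healing alone reduces
        person-cycles at risk and therefore admissions."""
        optimal_equal_hosp = replace(OPTIMAL, p_hosp=USUAL.p_hosp)
        t_u = run_cohort(USUAL, aggregate, bundle.settings)
        t_o = run_cohort(optimal_equal_hosp, aggregate, bundle.settings)
        out = count_outputs(t_u, t_o)
        assert out["hospitalisations_avoided"] > 0

    def test_doubling_usual_hazard_increases_avoided(self, bundle, aggregate):
        usual_hi = replace(
            USUAL,
            p_hosp=HorizonProbability(
                min(1.0, 2 * USUAL.p_hosp.value), USUAL.p_hosp.horizon_cycles
            ),
        )
        t_u = run_cohort(USUAL, aggregate, bundle.settings)
        t_hi = run_cohort(usual_hi, aggregate, bundle.settings)
        t_o = run_cohort(OPTIMAL, aggregate, bundle.settings)
        base = count_outputs(t_u, t_o)["hospitalisations_avoided"]
        high = count_outputs(t_hi, t_o)["hospitalisations_avoided"]
        assert high > base
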