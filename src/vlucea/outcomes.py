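"""Costing and accrual: resource-use schedules to payer-decomposed AUD and QALYs.

Each health state carries a recurring cost per person-fortnight and a one-off
cost per new entrant, assembled as frequency x unit cost from the care
schedules of each strategy:

* usual care — unhealed: twice-weekly clinic visits and dressing changes, high
  compression for 50% of patients, weekly pathology plus antibiotics for the
  infected share; one-off GP assessment on entry; no care once healed.
* optimal care Option 1 (nurse-practitioner wound clinics) — unhealed: weekly
  NP visit and dressing change, compression for everyone, weekly debridement
  plus antibiotics and a one-off pathology test for the infected share;
  one-off ABPI + NP + vascular-surgeon assessment; healed: 3-monthly NP
  review and compression stocking.
* optimal care Option 2 (trained GPs / community nurses / outpatient
  clinics) — as Option 1 with visits priced at the provider-mix-weighted
  rate, and a one-off ABPI + GP assessment; healed: 3-monthly GP review and
  stocking.

A hospital admission costs one episode payment, split 40% federal / 60%
State. Every other category is split among payers by the jurisdiction's
shares, except compression products: under optimal care they are fully
federally reimbursed, under usual care they are split between out-of-pocket
spending and indirect government funding by a configurable fraction.

Costs and QALYs accrue only to the affected sub-cohort (UNHEALED, HEALED
with history, HOSPITALISED); the never-affected susceptible pool accrues
neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import CohortTrace
from .parameters import (
    AnalysisSettings,
    CostCategory,
    CYCLES_PER_QUARTER,
    CYCLES_PER_YEAR,
    HealthState,
    JurisdictionProfile,
    N_STATES,
    Payer,
    PayerShares,
    StrategyParameters,
    UnitCosts,
    UtilitySet,
    ValidationError,
)

CATEGORIES = tuple(CostCategory)
PAYERS = tuple(Payer)
_CAT_IDX = {c: i for i, c in enumerate(CATEGORIES)}
_PAYER_IDX = {p: i for i, p in enumerate(PAYERS)}

DELIVERY_OPTIONS = (1, 2)


@dataclass(frozen=True)
class CycleCostSchedule:
    """Per-state costs for one (strategy, delivery option, jurisdiction).

    ``recurring[state, category, payer]`` is AUD per person-fortnight of
    occupancy; ``entry[state, category, payer]`` is AUD per new entrant.
    """

    strategy: str
    option: int
    jurisdiction: str
    recurring: np.ndarray  # (5 states, 5 categories, 3 payers)
    entry: np.ndarray

    def recurring_total(self, state: HealthState) -> float:
        return float(self.recurring[state].sum())

    def entry_total(self, state: HealthState) -> float:
        return float(self.entry[state].sum())


def _visit_price_mix(unit_costs: UnitCosts, jurisdiction: JurisdictionProfile) -> float:
    """Provider-mix-weighted price of one clinic visit (GP / community nurse /
    outpatient clinic)."""
    mix = jurisdiction.provider_mix
    return (
        mix.gp * unit_costs.gp_consult_aud
        + mix.community_nurse * unit_costs.community_nurse_visit_aud
        + mix.outpatient_clinic * unit_costs.outpatient_clinic_visit_aud
    )


def _compression_shares(strategy_name: str, settings: AnalysisSettings) -> PayerShares:
    if strategy_name == "optimal":
        # Compression products reimbursed by the Australian government.
        return PayerShares(1.0, 0.0, 0.0)
    f = settings.usual_compression_govt_share
    return PayerShares(f, 0.0, 1.0 - f)


def build_cost_schedule(
    unit_costs: UnitCosts,
    strategy: StrategyParameters,
    jurisdiction: JurisdictionProfile,
    option: int,
    settings: AnalysisSettings | None = None,
) -> CycleCostSchedule:
    """Assemble the per-cycle and per-entry state costs for one strategy arm.

    ``option`` selects the optimal-care delivery model (1 = NP-led specialist
    clinics, 2 = trained GP / community nursing / outpatient clinics); it is
    ignored for usual care, whose visits are always provider-mix priced.
    """
    if option not in DELIVERY_OPTIONS:
        raise ValidationError(f"delivery option must be one of {DELIVERY_OPTIONS}")
    settings = settings or AnalysisSettings()

    recurring = np.zeros((N_STATES, len(CATEGORIES), len(PAYERS)))
    entry = np.zeros_like(recurring)

    # Category totals before payer split: {state: {category: aud_per_cycle}}
    rec: dict[HealthState, dict[CostCategory, float]] = {
        s: {c: 0.0 for c in CATEGORIES} for s in HealthState
    }
    one: dict[HealthState, dict[CostCategory, float]] = {
        s: {c: 0.0 for c in CATEGORIES} for s in HealthState
    }

    uc = unit_costs
    infected = strategy.infection_share
    bandage_per_change = settings.bandages_per_dressing_change * uc.compression_bandage_aud

    if strategy.name == "usual":
        visits_per_cycle = 4.0  # twice a week
        dressings_per_cycle = 4.0
        rec[HealthState.UNHEALED][CostCategory.SERVICES] = (
            visits_per_cycle * _visit_price_mix(uc, jurisdiction)
            + infected * 2.0 * uc.pathology_test_aud  # pathology every week
        )
        rec[HealthState.UNHEALED][CostCategory.DRESSINGS] = (
            dressings_per_cycle * uc.dressing_change_aud
        )
        rec[HealthState.UNHEALED][CostCategory.COMPRESSION] = (
            dressings_per_cycle * bandage_per_change * strategy.compression_coverage
        )
        rec[HealthState.UNHEALED][CostCategory.MEDICINES] = (
            infected * uc.antibiotics_course_aud
        )
        one[HealthState.UNHEALED][CostCategory.SERVICES] = uc.gp_consult_aud
        # Healed: no additional care under usual arrangements.
    else:
        visits_per_cycle = 2.0  # once a week
        dressings_per_cycle = 2.0
        if option == 1:
            visit_price = uc.nurse_practitioner_consult_aud
            review_price = uc.nurse_practitioner_consult_aud
            entry_services = (
                uc.abpi_assessment_aud
                + uc.nurse_practitioner_consult_aud
                + uc.vascular_surgeon_consult_aud
            )
        else:
            visit_price = _visit_price_mix(uc, jurisdiction)
            review_price = uc.gp_consult_aud
            entry_services = uc.abpi_assessment_aud + uc.gp_consult_aud
        rec[HealthState.UNHEALED][CostCategory.SERVICES] = (
            visits_per_cycle * visit_price
            + infected * 2.0 * uc.debridement_session_aud  # debridement once a week
        )
        rec[HealthState.UNHEALED][CostCategory.DRESSINGS] = (
            dressings_per_cycle * uc.dressing_change_aud
        )
        rec[HealthState.UNHEALED][CostCategory.COMPRESSION] = (
            dressings_per_cycle * bandage_per_change * strategy.compression_coverage
        )
        rec[HealthState.UNHEALED][CostCategory.MEDICINES] = (
            infected * uc.antibiotics_course_aud
        )
        # One-off assessment bundle + a single pathology test for the infected.
        one[HealthState.UNHEALED][CostCategory.SERVICES] = (
            entry_services + infected * uc.pathology_test_aud
        )
        # Healed: 3-monthly review and compression stocking, amortised per cycle.
        rec[HealthState.HEALED][CostCategory.SERVICES] = review_price / CYCLES_PER_QUARTER
        rec[HealthState.HEALED][CostCategory.COMPRESSION] = (
            uc.compression_stocking_aud / CYCLES_PER_QUARTER
        )

    one[HealthState.HOSPITALISED][CostCategory.HOSPITAL] = uc.hospitalisation_aud

    shares = dict(jurisdiction.payer_shares)
    shares[CostCategory.COMPRESSION] = _compression_shares(strategy.name, settings)

    for state in HealthState:
        for cat in CATEGORIES:
            split = shares[cat]
            for payer in PAYERS:
                recurring[state, _CAT_IDX[cat], _PAYER_IDX[payer]] = (
                    rec[state][cat] * split[payer]
                )
                entry[state, _CAT_IDX[cat], _PAYER_IDX[payer]] = (
                    one[state][cat] * split[payer]
                )

    return CycleCostSchedule(
        strategy=strategy.name,
        option=option,
        jurisdiction=jurisdiction.name,
        recurring=recurring,
        entry=entry,
    )


def discount_factor(t: float | np.ndarray, rate_per_year: float) -> float | np.ndarray:
    """Present-value multiplier for cycle index ``t``: (1 + r)^(-t/26)."""
    return (1.0 + rate_per_year) ** (-np.asarray(t, dtype=float) / CYCLES_PER_YEAR)


@dataclass(frozen=True)
class EconResult:
    """Discounted (and undiscounted) totals for one strategy arm."""

    strategy: str
    option: int
    jurisdiction: str
    cost: np.ndarray  # (5 categories, 3 payers), discounted AUD
    cost_undiscounted: np.ndarray
    qalys: float
    qalys_undiscounted: float
    persons_ever_affected: float
    hospitalisations: float

    @property
    def total_cost(self) -> float:
        return float(self.cost.sum())

    def cost_by_payer(self, payer: Payer) -> float:
        return float(self.cost[:, _PAYER_IDX[payer]].sum())

    def cost_by_category(self, category: CostCategory) -> float:
        return float(self.cost[_CAT_IDX[category], :].sum())

    def cost_component(self, category: CostCategory, payer: Payer) -> float:
        return float(self.cost[_CAT_IDX[category], _PAYER_IDX[payer]])

    @property
    def health_system_cost(self) -> float:
        """Costs borne by governments (total minus out-of-pocket)."""
        return self.total_cost - self.cost_by_payer(Payer.OUT_OF_POCKET)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CATEGORIES:
            for payer in PAYERS:
                rows.append(
                    {
                        "strategy": self.strategy,
                        "option": self.option,
                        "jurisdiction": self.jurisdiction,
                        "category": cat.value,
                        "payer": payer.value,
                        "cost_aud": self.cost_component(cat, payer),
                    }
                )
        return pd.DataFrame(rows)

    def __add__(self, other: "EconResult") -> "EconResult":
        if (self.strategy, self.option) != (other.strategy, other.option):
            raise ValidationError("can only add results of the same strategy/option")
        return EconResult(
            strategy=self.strategy,
            option=self.option,
            jurisdiction="AGGREGATE",
            cost=self.cost + other.cost,
            cost_undiscounted=self.cost_undiscounted + other.cost_undiscounted,
            qalys=self.qalys + other.qalys,
            qalys_undiscounted=self.qalys_undiscounted + other.qalys_undiscounted,
            persons_ever_affected=self.persons_ever_affected + other.persons_ever_affected,
            hospitalisations=self.hospitalisations + other.hospitalisations,
        )


def accrue(
    trace: CohortTrace,
    schedule: CycleCostSchedule,
    utilities: UtilitySet,
    settings: AnalysisSettings,
) -> EconResult:
    """Accumulate discounted costs and QALYs over a cohort trace.

    Recurring costs and QALYs are valued on start-of-cycle occupancy over the
    ``n_cycles`` cycles actually lived (optionally half-cycle corrected);
    one-off entry costs are charged when the flow arrives, including the
    prevalent cohort at cycle 0 and events arriving at the final time point.
    """
    n = trace.n_cycles
    t_all = np.arange(n + 1)
    disc = discount_factor(t_all, settings.discount_rate_per_year)

    occ = trace.occupancy.astype(float).copy()
    if settings.half_cycle_correction:
        # Average of start- and end-of-cycle occupancy for each lived cycle.
        occ_cycle = 0.5 * (occ[:-1] + occ[1:])
    else:
        occ_cycle = occ[:-1]
    disc_cycle = disc[:-1]

    # Recurring costs: sum over states of occupancy x per-cycle cost.
    rec_by_state = schedule.recurring  # (5, cat, payer)
    cost = np.zeros((len(CATEGORIES), len(PAYERS)))
    cost_undisc = np.zeros_like(cost)
    for s in HealthState:
        person_cycles_disc = float(occ_cycle[:, s] @ disc_cycle)
        person_cycles = float(occ_cycle[:, s].sum())
        cost += rec_by_state[s] * person_cycles_disc
        cost_undisc += rec_by_state[s] * person_cycles

    # One-off entry costs at arrival time.
    entrants_u = trace.entrants_incident + trace.entrants_recurrent
    if settings.entry_cost_on_discharge:
        entrants_u = entrants_u + trace.entrants_discharge
    cost += schedule.entry[HealthState.UNHEALED] * float(entrants_u @ disc)
    cost_undisc += schedule.entry[HealthState.UNHEALED] * float(entrants_u.sum())
    cost += schedule.entry[HealthState.HOSPITALISED] * float(trace.admissions @ disc)
    cost_undisc += schedule.entry[HealthState.HOSPITALISED] * float(
        trace.admissions.sum()
    )

    # QALYs: affected states only, utility per year x fortnight fraction.
    qalys = 0.0
    qalys_undisc = 0.0
    for s in (HealthState.UNHEALED, HealthState.HEALED, HealthState.HOSPITALISED):
        u = utilities.for_state(s) * settings.cycle_length_years
        qalys += u * float(occ_cycle[:, s] @ disc_cycle)
        qalys_undisc += u * float(occ_cycle[:, s].sum())

    return EconResult(
        strategy=schedule.strategy,
        option=schedule.option,
        jurisdiction=schedule.jurisdiction,
        cost=cost,
        cost_undiscounted=cost_undisc,
        qalys=qalys,
        qalys_undiscounted=qalys_undisc,
        persons_ever_affected=float(trace.cumulative_incident[-1]),
        hospitalisations=float(trace.cumulative_hospitalisations[-1]),
    )


def count_outputs(
    trace_usual: CohortTrace, trace_optimal: CohortTrace
) -> dict[str, float]:
    """Headline person counts: ever-affected per arm, hospitalisations avoided."""
    return {
        "affected_usual": float(trace_usual.cumulative_incident[-1]),
        "affected_optimal": float(trace_optimal.cumulative_incident[-1]),
        "hospitalisations_usual": float(trace_usual.cumulative_hospitalisations[-1]),
        "hospitalisations_optimal": float(
            trace_optimal.cumulative_hospitalisations[-1]
        ),
        "hospitalisations_avoided": float(
            trace_usual.cumulative_hospitalisations[-1]
            - trace_optimal.cumulative_hospitalisations[-1]
        ),
    }


__all__ = [
    "CATEGORIES",
    "CycleCostSchedule",
    "DELIVERY_OPTIONS",
    "EconResult",
    "PAYERS",
    "accrue",
    "build_cost_schedule",
    "count_outputs",
    "discount_factor",
]
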