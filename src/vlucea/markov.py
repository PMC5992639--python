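"""Cohort engine: transition matrices and fortnightly cohort iteration.

The cohort model tracks expected state occupancy (fractional persons) of the
60+ population over 131 time points. The NO_VLU column holds only the
never-affected susceptible pool: the state structure has no path back to
NO_VLU, so everyone outside that column has a VLU history and belongs to the
affected sub-cohort for costing purposes. Population growth (people turning
60) enters the susceptible pool after each cycle's transitions and is not
exposed to that cycle's mortality.

A vectorised individual-level microsimulation with the same per-cycle
probabilities serves as an independent oracle for the cohort expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    AnalysisSettings,
    HealthState,
    HorizonProbability,
    JurisdictionProfile,
    N_STATES,
    StrategyParameters,
    ValidationError,
    to_per_cycle,
)

_N = HealthState.NO_VLU
_U = HealthState.UNHEALED
_H = HealthState.HEALED
_X = HealthState.HOSPITALISED
_D = HealthState.DEAD


def build_matrix(
    strategy: StrategyParameters,
    mortality: HorizonProbability | None = None,
    discharge_destination: str = "unhealed",
) -> np.ndarray:
    """Assemble the 5x5 per-fortnight transition matrix for one strategy.

    Exit probabilities are the per-cycle conversions of the strategy's native
    inputs; the probability of staying put is one minus the sum of exits.
    Competing exits are simply summed (no cause-elimination correction); if
    the exits of any row exceed 1 after conversion the inputs are invalid.

    ``mortality`` overrides the strategy's all-cause mortality (used to apply
    jurisdiction-specific rates). Hospital stays last exactly one cycle:
    survivors are discharged to ``discharge_destination``.
    """
    p_mort = to_per_cycle(mortality if mortality is not None else strategy.mortality)
    p_inc = to_per_cycle(strategy.incidence)
    p_heal = to_per_cycle(strategy.p_heal)
    p_hosp = to_per_cycle(strategy.p_hosp)
    p_recur = to_per_cycle(strategy.p_recur)
    if discharge_destination not in ("unhealed", "healed"):
        raise ValidationError(
            f"discharge_destination must be 'unhealed' or 'healed', "
            f"got {discharge_destination!r}"
        )

    m = np.zeros((N_STATES, N_STATES))
    m[_N, _U] = p_inc
    m[_N, _D] = p_mort
    m[_U, _H] = p_heal
    m[_U, _X] = p_hosp
    m[_U, _D] = p_mort
    m[_H, _U] = p_recur
    m[_H, _D] = p_mort
    discharge_to = _U if discharge_destination == "unhealed" else _H
    m[_X, discharge_to] = 1.0 - p_mort
    m[_X, _D] = p_mort
    m[_D, _D] = 1.0

    for s in (_N, _U, _H):
        exits = m[s].sum()
        if exits > 1.0 + 1e-12:
            raise ValidationError(
                f"exit probabilities of state {HealthState(s).name} sum to "
                f"{exits:.6f} > 1 after per-cycle conversion"
            )
        m[s, s] = 1.0 - exits
    return m


def validate_matrix(m: np.ndarray, atol: float = 1e-12) -> None:
    """Check stochasticity and the structural zeros of the state diagram."""
    if m.shape != (N_STATES, N_STATES):
        raise ValidationError(f"matrix must be {N_STATES}x{N_STATES}, got {m.shape}")
    if (m < -atol).any() or (m > 1 + atol).any():
        raise ValidationError("matrix entries must lie in [0, 1]")
    if not np.allclose(m.sum(axis=1), 1.0, atol=atol):
        raise ValidationError("matrix rows must sum to 1")
    structural_zero = [
        (_N, _H), (_N, _X), (_H, _N), (_H, _X), (_X, _X), (_U, _N), (_D, _N),
        (_D, _U), (_D, _H), (_D, _X),
    ]
    for i, j in structural_zero:
        if abs(m[i, j]) > atol:
            raise ValidationError(
                f"structural zero violated: {HealthState(i).name}->"
                f"{HealthState(j).name} = {m[i, j]!r}"
            )


@dataclass
class CohortTrace:
    """State occupancy and event flows of one cohort run.

    ``occupancy[t, s]`` is the expected number of persons in state ``s`` at
    the start of cycle ``t``; the NO_VLU column is the never-affected
    susceptible pool. Flow arrays are indexed by the cycle at whose *end* the
    flow arrives, so ``entrants_incident[0]`` holds the prevalent cohort
    placed in UNHEALED at initialisation.
    """

    occupancy: np.ndarray  # (n_cycles + 1, 5)
    entrants_incident: np.ndarray  # NO_VLU -> UNHEALED flow arriving at t
    entrants_recurrent: np.ndarray  # HEALED -> UNHEALED flow arriving at t
    entrants_discharge: np.ndarray  # HOSPITALISED -> UNHEALED flow arriving at t
    admissions: np.ndarray  # UNHEALED -> HOSPITALISED flow arriving at t
    deaths: np.ndarray  # flow into DEAD arriving at t
    growth_inflow: np.ndarray  # persons added to the susceptible pool at t

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def new_entrants_unhealed(self) -> np.ndarray:
        """All flows into UNHEALED per time point (incident + recurrent +
        hospital discharges)."""
        return self.entrants_incident + self.entrants_recurrent + self.entrants_discharge

    @property
    def cumulative_incident(self) -> np.ndarray:
        """Persons ever affected by a VLU up to each time point."""
        return np.cumsum(self.entrants_incident)

    @property
    def cumulative_hospitalisations(self) -> np.ndarray:
        return np.cumsum(self.admissions)

    @property
    def cumulative_deaths(self) -> np.ndarray:
        return np.cumsum(self.deaths)

    @property
    def total_persons(self) -> np.ndarray:
        return self.occupancy.sum(axis=1)

    def check_conservation(self, atol: float = 1e-6) -> None:
        """Total occupancy must equal the initial population plus cumulative
        growth inflow at every time point (deaths stay counted in DEAD)."""
        expected = self.total_persons[0] + np.cumsum(self.growth_inflow) - self.growth_inflow[0]
        if not np.allclose(self.total_persons, expected, atol=atol):
            worst = np.abs(self.total_persons - expected).max()
            raise ValidationError(f"person conservation violated by {worst!r}")
        if (self.occupancy < -atol).any():
            raise ValidationError("negative occupancy in trace")

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: one row per time point, explicit units in headers."""
        df = pd.DataFrame(
            self.occupancy,
            columns=[f"{s.name.lower()}_persons" for s in HealthState],
        )
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["entrants_incident_persons"] = self.entrants_incident
        df["entrants_recurrent_persons"] = self.entrants_recurrent
        df["entrants_discharge_persons"] = self.entrants_discharge
        df["admissions_persons"] = self.admissions
        df["deaths_persons"] = self.deaths
        df["growth_inflow_persons"] = self.growth_inflow
        df["cumulative_incident_persons"] = self.cumulative_incident
        df["cumulative_hospitalisations_events"] = self.cumulative_hospitalisations
        return df


def initialise_cohort(
    jurisdiction: JurisdictionProfile, prevalence: float
) -> np.ndarray:
    """Occupancy at cycle 0: the prevalent fraction starts in UNHEALED
    (rounded to whole persons), everyone else in the susceptible pool."""
    if not (0.0 <= prevalence <= 1.0):
        raise ValidationError(f"prevalence must lie in [0, 1], got {prevalence!r}")
    occ = np.zeros(N_STATES)
    unhealed = float(round(prevalence * jurisdiction.population_60plus))
    occ[_U] = unhealed
    occ[_N] = jurisdiction.population_60plus - unhealed
    return occ


def step(
    occupancy: np.ndarray, matrix: np.ndarray, growth_per_cycle: float = 0.0
) -> tuple[np.ndarray, dict[str, float]]:
    """Advance one fortnight: apply the transition matrix, then add the
    growth inflow to the susceptible pool. Returns (next occupancy, flows)."""
    if (occupancy < 0).any():
        raise ValidationError("negative occupancy passed to step")
    flows = occupancy[:, None] * matrix
    nxt = flows.sum(axis=0)
    nxt[_N] += growth_per_cycle
    tallies = {
        "incident": flows[_N, _U],
        "recurrent": flows[_H, _U],
        "admissions": flows[_U, _X],
        "discharges": flows[_X, _U] + flows[_X, _H],
        "deaths": flows[:, _D].sum() - occupancy[_D],
        "growth": growth_per_cycle,
    }
    return nxt, tallies


def run_cohort(
    strategy: StrategyParameters,
    jurisdiction: JurisdictionProfile,
    settings: AnalysisSettings,
) -> CohortTrace:
    """Deterministic cohort run over ``settings.n_cycles`` fortnights."""
    matrix = build_matrix(
        strategy,
        mortality=jurisdiction.mortality,
        discharge_destination=settings.discharge_destination,
    )
    n = settings.n_cycles
    occ = np.zeros((n + 1, N_STATES))
    occ[0] = initialise_cohort(jurisdiction, settings.prevalence_at_cycle0)

    incident = np.zeros(n + 1)
    recurrent = np.zeros(n + 1)
    discharge = np.zeros(n + 1)
    admissions = np.zeros(n + 1)
    deaths = np.zeros(n + 1)
    growth = np.zeros(n + 1)
    # The prevalent cohort counts as entrants (and ever-affected) at t = 0.
    incident[0] = occ[0, _U]

    for t in range(1, n + 1):
        occ[t], tallies = step(occ[t - 1], matrix, jurisdiction.growth_per_cycle)
        incident[t] = tallies["incident"]
        recurrent[t] = tallies["recurrent"]
        discharge[t] = tallies["discharges"] if settings.discharge_destination == "unhealed" else 0.0
        admissions[t] = tallies["admissions"]
        deaths[t] = tallies["deaths"]
        growth[t] = tallies["growth"]

    return CohortTrace(
        occupancy=occ,
        entrants_incident=incident,
        entrants_recurrent=recurrent,
        entrants_discharge=discharge,
        admissions=admissions,
        deaths=deaths,
        growth_inflow=growth,
    )


def microsim_oracle(
    strategy: StrategyParameters,
    jurisdiction: JurisdictionProfile,
    settings: AnalysisSettings,
    n_individuals: int,
    seed: int,
) -> CohortTrace:
    """Individual-level Monte-Carlo simulation with the same per-cycle
    probabilities, as an independent check on the cohort expectations.

    The jurisdiction's population is represented by ``n_individuals``
    simulated people; the growth inflow is scaled accordingly and added as
    whole individuals with a fractional-remainder carry so cumulative inflow
    matches the cohort model to within one person.
    """
    if n_individuals <= 0:
        raise ValidationError("n_individuals must be > 0")
    rng = np.random.default_rng(seed)
    matrix = build_matrix(
        strategy,
        mortality=jurisdiction.mortality,
        discharge_destination=settings.discharge_destination,
    )
    cum = np.cumsum(matrix, axis=1)

    pop = jurisdiction.population_60plus
    scale = n_individuals / pop if pop > 0 else 0.0
    n_unhealed = int(round(settings.prevalence_at_cycle0 * n_individuals))
    states = np.full(n_individuals, int(_N), dtype=np.int64)
    states[:n_unhealed] = int(_U)
    growth_scaled = jurisdiction.growth_per_cycle * scale

    n = settings.n_cycles
    occ = np.zeros((n + 1, N_STATES))
    incident = np.zeros(n + 1)
    recurrent = np.zeros(n + 1)
    discharge = np.zeros(n + 1)
    admissions = np.zeros(n + 1)
    deaths = np.zeros(n + 1)
    growth = np.zeros(n + 1)
    occ[0] = np.bincount(states, minlength=N_STATES)
    incident[0] = n_unhealed

    carry = 0.0
    for t in range(1, n + 1):
        u = rng.random(states.size)
        nxt = (u[:, None] > cum[states]).sum(axis=1).astype(np.int64)
        incident[t] = np.count_nonzero((states == _N) & (nxt == _U))
        recurrent[t] = np.count_nonzero((states == _H) & (nxt == _U))
        admissions[t] = np.count_nonzero((states == _U) & (nxt == _X))
        discharge[t] = np.count_nonzero((states == _X) & (nxt == _U))
        deaths[t] = np.count_nonzero((states != _D) & (nxt == _D))
        carry += growth_scaled
        n_new = int(carry)
        carry -= n_new
        growth[t] = n_new
        states = np.concatenate(
            [nxt, np.full(n_new, int(_N), dtype=np.int64)]
        )
        occ[t] = np.bincount(states, minlength=N_STATES)

    return CohortTrace(
        occupancy=occ,
        entrants_incident=incident,
        entrants_recurrent=recurrent,
        entrants_discharge=discharge,
        admissions=admissions,
        deaths=deaths,
        growth_inflow=growth,
    )


__all__ = [
    "CohortTrace",
    "build_matrix",
    "initialise_cohort",
    "microsim_oracle",
    "run_cohort",
    "step",
    "validate_matrix",
]
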