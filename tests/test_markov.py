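"""Transition matrix structure and cohort iteration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vlucea.markov import (
    build_matrix,
    initialise_cohort,
    microsim_oracle,
    run_cohort,
    step,
    validate_matrix,
)
from dataclasses import replace

from vlucea.parameters import (
    CYCLES_PER_YEAR,
    HealthState,
    HorizonProbability,
    ValidationError,
    baseline_strategies,
    compose_cycles,
)

USUAL, OPTIMAL = baseline_strategies()


def _strategy(p_heal=0.0, p_recur=0.0, p_hosp=0.0, incidence=0.0, mortality=0.0):
    return replace(
        USUAL,
        p_heal=HorizonProbability(p_heal, 1.0),
        p_recur=HorizonProbability(p_recur, 1.0),
        p_hosp=HorizonProbability(p_hosp, 1.0),
        incidence=HorizonProbability(incidence, 1.0),
        mortality=HorizonProbability(mortality, 1.0),
    )


class TestBuildMatrix:
    @pytest.mark.parametrize("strategy", [USUAL, OPTIMAL], ids=["usual", "optimal"])
    def test_rows_stochastic_and_structure(self, strategy):
        m = build_matrix(strategy)
        validate_matrix(m)
        exits = m[HealthState.UNHEALED]
        for to in (HealthState.HEALED, HealthState.HOSPITALISED, HealthState.DEAD):
            assert 0.0 < exits[to] < 1.0

    def test_all_zero_exits_gives_identity_like_matrix(self):
        expected = np.eye(5)
        # hospital stays still last one cycle: survivors discharge with certainty
        expected[HealthState.HOSPITALISED, HealthState.HOSPITALISED] = 0.0
        expected[HealthState.HOSPITALISED, HealthState.UNHEALED] = 1.0
        assert np.array_equal(build_matrix(_strategy()), expected)

    def test_usual_hospitalisation_hazard_recomposes_to_annual_rate(self):
        m = build_matrix(USUAL)
        annual = compose_cycles(
            m[HealthState.UNHEALED, HealthState.HOSPITALISED], CYCLES_PER_YEAR
        )
        assert annual == pytest.approx(0.0534, abs=5e-5)

    def test_discharge_destination_switch(self):
        m_u = build_matrix(OPTIMAL, discharge_destination="unhealed")
        m_h = build_matrix(OPTIMAL, discharge_destination="healed")
        assert m_u[HealthState.HOSPITALISED, HealthState.UNHEALED] > 0.99
        assert m_h[HealthState.HOSPITALISED, HealthState.HEALED] > 0.99

    def test_exits_above_one_rejected(self):
        bad = _strategy(p_heal=0.7, p_hosp=0.5, mortality=0.2)
        with pytest.raises(ValidationError, match="UNHEALED"):
            build_matrix(bad)


class TestInitialiseCohort:
    @pytest.mark.parametrize(
        "prevalence,expected",
        [(0.0033, 15_973), (0.005, 24_202), (0.01, 48_404), (0.0169, 81_803)],
    )
    def test_national_cycle0_counts(self, aggregate, prevalence, expected):
        occ = initialise_cohort(aggregate, prevalence)
        assert occ[HealthState.UNHEALED] == expected
        assert occ.sum() == aggregate.population_60plus

    def test_zero_prevalence(self, aggregate):
        occ = initialise_cohort(aggregate, 0.0)
        assert occ[HealthState.NO_VLU] == aggregate.population_60plus
        assert occ[1:].sum() == 0.0


class TestStep:
    def test_identity_matrix_preserves_occupancy(self):
        m = build_matrix(_strategy())
        occ = np.array([100.0, 50.0, 20.0, 0.0, 5.0])
        nxt, tallies = step(occ, m, growth_per_cycle=0.0)
        assert np.allclose(nxt, occ)
        assert tallies["admissions"] == 0.0

    def test_growth_only_enters_susceptible_pool(self):
        m = build_matrix(_strategy())
        occ = np.array([100.0, 50.0, 0.0, 0.0, 0.0])
        nxt, _ = step(occ, m, growth_per_cycle=7.0)
        assert nxt[HealthState.NO_VLU] == 107.0
        assert nxt[HealthState.UNHEALED] == 50.0

    def test_negative_occupancy_rejected(self):
        m = build_matrix(USUAL)
        with pytest.raises(ValidationError):
            step(np.array([-1.0, 0, 0, 0, 0]), m)


class TestRunCohort:
    def test_zero_cycles_equals_initialisation(self, bundle, aggregate):
        settings = replace(bundle.settings, n_cycles=0)
        trace = run_cohort(USUAL, aggregate, settings)
        assert trace.occupancy.shape == (1, 5)
        assert trace.occupancy[0, HealthState.UNHEALED] == 15_973

    def test_deterministic(self, bundle, aggregate):
        t1 = run_cohort(USUAL, aggregate, bundle.settings)
        t2 = run_cohort(USUAL, aggregate, bundle.settings)
        assert np.array_equal(t1.occupancy, t2.occupancy)

    @pytest.mark.parametrize("strategy", [USUAL, OPTIMAL], ids=["usual", "optimal"])
    def test_conservation_and_monotone_tallies(self, bundle, aggregate, strategy):
        trace = run_cohort(strategy, aggregate, bundle.settings)
        trace.check_conservation(atol=1e-6)
        assert (np.diff(trace.occupancy[:, HealthState.DEAD]) >= -1e-9).all()
        assert (np.diff(trace.cumulative_hospitalisations) >= 0).all()
        assert (np.diff(trace.cumulative_incident) >= 0).all()
        # susceptible pool only shrinks apart from growth inflow
        sus = trace.occupancy[:, HealthState.NO_VLU]
        assert (np.diff(sus) <= trace.growth_inflow[1:] + 1e-9).all()

    def test_over_300k_ever_affected_nationally(self, bundle, aggregate):
        for strategy in (USUAL, OPTIMAL):
            trace = run_cohort(strategy, aggregate, bundle.settings)
            assert trace.cumulative_incident[-1] > 300_000

    def test_usual_care_has_more_hospitalisations(self, bundle, aggregate):
        t_u = run_cohort(USUAL, aggregate, bundle.settings)
        t_o = run_cohort(OPTIMAL, aggregate, bundle.settings)
        assert (
            t_u.cumulative_hospitalisations[-1] > t_o.cumulative_hospitalisations[-1]
        )

    @given(bump=st.floats(0.01, 0.3, allow_nan=False))
    def test_raising_heal_probability_lowers_unhealed_occupancy(
        self, bundle, aggregate, bump
    ):
        base = run_cohort(USUAL, aggregate, bundle.settings)
        p = USUAL.p_heal
        raised = replace(
            USUAL, p_heal=HorizonProbability(min(1.0, p.value + bump), p.horizon_cycles)
        )
        high = run_cohort(raised, aggregate, bundle.settings)
        u_base = base.occupancy[1:, HealthState.UNHEALED]
        u_high = high.occupancy[1:, HealthState.UNHEALED]
        assert (u_high <= u_base + 1e-9).all()


class TestMicrosimOracle:
    def test_single_individual_path_is_legal(self, bundle, aggregate):
        settings = replace(bundle.settings, n_cycles=30, prevalence_at_cycle0=1.0)
        trace = microsim_oracle(USUAL, aggregate, settings, n_individuals=1, seed=3)
        assert np.allclose(trace.occupancy.sum(axis=1), 1 + np.cumsum(trace.growth_inflow))
        # never occupies NO_VLU: one affected individual cannot re-enter it
        assert trace.occupancy[:, HealthState.NO_VLU].sum() == 0.0

    def test_degenerate_heal_probability_empties_unhealed(self, bundle, aggregate):
        strategy = _strategy(p_heal=1.0)
        settings = replace(
            bundle.settings, n_cycles=2, prevalence_at_cycle0=0.5
        )
        juris = replace(aggregate, growth_per_cycle=0.0, population_60plus=1000.0,
                        mortality=HorizonProbability(0.0, 26.0))
        trace = microsim_oracle(strategy, juris, settings, n_individuals=200, seed=0)
        assert trace.occupancy[0, HealthState.UNHEALED] == 100
        assert trace.occupancy[1, HealthState.UNHEALED] == 0
        assert trace.occupancy[1, HealthState.HEALED] == 100

    def test_matches_cohort_expectation_small(self, bundle, aggregate):
        """Occupancy proportions agree with the cohort model within three
        binomial standard errors at a modest sample size."""
        settings = replace(bundle.settings, n_cycles=40)
        n = 20_000
        scaled = replace(
            aggregate,
            population_60plus=float(n),
            growth_per_cycle=aggregate.growth_per_cycle
            * n
            / aggregate.population_60plus,
        )
        sim = microsim_oracle(USUAL, scaled, settings, n_individuals=n, seed=11)
        cohort = run_cohort(USUAL, scaled, settings)
        p = cohort.occupancy / cohort.total_persons[:, None]
        p_hat = sim.occupancy / sim.total_persons[:, None]
        se = np.sqrt(p * (1 - p) / sim.total_persons[:, None])
        assert (np.abs(p_hat - p) <= 3 * se + 2.0 / n).all()
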