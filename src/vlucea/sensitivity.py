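"""Sensitivity analyses: one-way deterministic (tornado), scenarios, and PSA.

The probabilistic sensitivity analysis draws transition probabilities,
infection shares and utilities from beta distributions and unit costs from
gamma distributions, each matched by method of moments to the baseline mean
with standard deviation cv x mean. The source description fixes the
distribution families but not their spreads; the coefficient of variation
(default 0.2) is therefore the single most consequential assumption behind
the PSA results and is exposed in the analysis settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    AGGREGATE_NAME,
    CYCLES_PER_YEAR,
    HorizonProbability,
    ModelConfig,
    StrategyParameters,
    UnitCosts,
    UtilitySet,
    ValidationError,
)
from .pipeline import ComparisonResult, run_comparison, run_national

log = logging.getLogger(__name__)

#: Default lambda grid for the acceptability curve: 0-150k AUD/QALY in 5k
#: steps, always including the 64k willingness-to-pay threshold.
DEFAULT_WTP_GRID = tuple(sorted(set(range(0, 150_001, 5_000)) | {64_000}))

#: Scenario values for the usual-care annual hospitalisation rate: the
#: optimal-care rate (low), the baseline restatement, and the high estimate
#: from leg-ulcer-complication admissions data.
HOSPITALISATION_SCENARIOS = (0.0116, 0.0534, 0.1236)

#: Scenario values for VLU prevalence among the 60+ population.
PREVALENCE_SCENARIOS = (0.0033, 0.005, 0.01, 0.0169)


def _run(config: ModelConfig, jurisdiction: str, option: int) -> ComparisonResult:
    if jurisdiction == AGGREGATE_NAME and not any(
        j.name == AGGREGATE_NAME for j in config.jurisdictions
    ):
        return run_national(config, option)
    return run_comparison(config, jurisdiction, option)


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DsaParameter:
    """One tunable input with its low/high endpoints and a setter that
    returns a new config with the value replaced."""

    name: str
    baseline: float
    low: float
    high: float
    setter: Callable[[ModelConfig, float], ModelConfig]


@dataclass(frozen=True)
class TornadoEntry:
    """Outcomes at the two endpoints of one one-way sensitivity analysis."""

    parameter: str
    low_value: float
    high_value: float
    nmb_low: float
    nmb_high: float
    delta_cost_low: float
    delta_cost_high: float
    delta_qaly_low: float
    delta_qaly_high: float
    icer_class_low: str
    icer_class_high: str

    @property
    def width(self) -> float:
        """Tornado bar width: the NMB swing between the two endpoints."""
        return abs(self.nmb_high - self.nmb_low)


def _set_strategy_prob(
    strategy_name: str, attr: str
) -> Callable[[ModelConfig, float], ModelConfig]:
    def setter(config: ModelConfig, value: float) -> ModelConfig:
        strat: StrategyParameters = config.strategy(strategy_name)
        hp: HorizonProbability = getattr(strat, attr)
        new_strat = replace(strat, **{attr: HorizonProbability(value, hp.horizon_cycles)})
        return replace(config, **{strategy_name: new_strat})

    return setter


def _set_both_strategy_prob(attr: str) -> Callable[[ModelConfig, float], ModelConfig]:
    def setter(config: ModelConfig, value: float) -> ModelConfig:
        for name in ("usual", "optimal"):
            strat = config.strategy(name)
            hp = getattr(strat, attr)
            config = replace(
                config,
                **{name: replace(strat, **{attr: HorizonProbability(value, hp.horizon_cycles)})},
            )
        # Shared inputs also drive jurisdiction profiles where applicable.
        if attr == "mortality":
            config = replace(
                config,
                jurisdictions=tuple(
                    replace(j, mortality=HorizonProbability(value, j.mortality.horizon_cycles))
                    for j in config.jurisdictions
                ),
            )
        return config

    return setter


def _set_utility(attr: str) -> Callable[[ModelConfig, float], ModelConfig]:
    def setter(config: ModelConfig, value: float) -> ModelConfig:
        return replace(config, utilities=replace(config.utilities, **{attr: value}))

    return setter


def _set_unit_cost(attr: str) -> Callable[[ModelConfig, float], ModelConfig]:
    def setter(config: ModelConfig, value: float) -> ModelConfig:
        return replace(config, unit_costs=replace(config.unit_costs, **{attr: value}))

    return setter


def _set_usual_hosp_annual(config: ModelConfig, value: float) -> ModelConfig:
    """Replace the usual-care hospitalisation input with an annual rate."""
    return replace(
        config,
        usual=replace(
            config.usual, p_hosp=HorizonProbability(value, CYCLES_PER_YEAR)
        ),
    )


def _rel_range(x: float, rel: float, cap: float | None = 1.0) -> tuple[float, float]:
    low = max(0.0, x * (1.0 - rel))
    high = x * (1.0 + rel)
    if cap is not None:
        high = min(cap, high)
    return low, high


def default_dsa_parameters(config: ModelConfig) -> list[DsaParameter]:
    """The published model inputs, each varied over +/- the configured
    relative range (truncated to its domain); the usual-care hospitalisation
    rate instead spans its scenario range."""
    rel = config.settings.dsa_rel_range
    params: list[DsaParameter] = []

    prob_specs = [
        ("usual", "p_heal", "usual_p_heal_3month"),
        ("usual", "p_recur", "usual_p_recur_annual"),
        ("optimal", "p_heal", "optimal_p_heal_3month"),
        ("optimal", "p_recur", "optimal_p_recur_annual"),
        ("optimal", "p_hosp", "optimal_p_hosp_annual"),
    ]
    for strat_name, attr, label in prob_specs:
        base = getattr(config.strategy(strat_name), attr).value
        low, high = _rel_range(base, rel)
        params.append(
            DsaParameter(label, base, low, high, _set_strategy_prob(strat_name, attr))
        )

    # Usual-care hospitalisation: scenario range, on the annual scale.
    params.append(
        DsaParameter(
            "usual_p_hosp_annual",
            HOSPITALISATION_SCENARIOS[1],
            HOSPITALISATION_SCENARIOS[0],
            HOSPITALISATION_SCENARIOS[2],
            _set_usual_hosp_annual,
        )
    )

    for attr, label in [("incidence", "incidence_annual")]:
        base = getattr(config.usual, attr).value
        low, high = _rel_range(base, rel)
        params.append(DsaParameter(label, base, low, high, _set_both_strategy_prob(attr)))

    for attr in ("u_healed", "u_unhealed"):
        base = getattr(config.utilities, attr)
        low, high = _rel_range(base, rel)
        params.append(DsaParameter(attr, base, low, high, _set_utility(attr)))

    for attr in ("hospitalisation_aud", "compression_bandage_aud", "dressing_change_aud"):
        base = getattr(config.unit_costs, attr)
        low, high = _rel_range(base, rel, cap=None)
        params.append(DsaParameter(attr, base, low, high, _set_unit_cost(attr)))

    return params


def one_way_dsa(
    config: ModelConfig,
    parameters: Sequence[DsaParameter] | None = None,
    jurisdiction: str = AGGREGATE_NAME,
    option: int = 1,
) -> list[TornadoEntry]:
    """Re-run the full pipeline at each parameter's low and high endpoint,
    holding everything else at baseline. Entries are sorted widest first."""
    if parameters is None:
        parameters = default_dsa_parameters(config)
    wtp = config.settings.wtp_aud_per_qaly
    entries = []
    for p in parameters:
        results = {}
        for side, value in (("low", p.low), ("high", p.high)):
            cfg = p.setter(config, value)
            cmp_res = _run(cfg, jurisdiction, option)
            results[side] = cmp_res.delta
        entries.append(
            TornadoEntry(
                parameter=p.name,
                low_value=p.low,
                high_value=p.high,
                nmb_low=results["low"].nmb(wtp),
                nmb_high=results["high"].nmb(wtp),
                delta_cost_low=results["low"].delta_cost,
                delta_cost_high=results["high"].delta_cost,
                delta_qaly_low=results["low"].delta_qaly,
                delta_qaly_high=results["high"].delta_qaly,
                icer_class_low=results["low"].icer_class,
                icer_class_high=results["high"].icer_class,
            )
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "nmb_low_aud": [e.nmb_low for e in entries],
            "nmb_high_aud": [e.nmb_high for e in entries],
            "delta_cost_low_aud": [e.delta_cost_low for e in entries],
            "delta_cost_high_aud": [e.delta_cost_high for e in entries],
            "delta_qaly_low": [e.delta_qaly_low for e in entries],
            "delta_qaly_high": [e.delta_qaly_high for e in entries],
            "width_nmb_aud": [e.width for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Scenario analyses
# ---------------------------------------------------------------------------


def scenario_hospitalisation(
    config: ModelConfig,
    annual_rates: Sequence[float] = HOSPITALISATION_SCENARIOS,
    jurisdiction: str = AGGREGATE_NAME,
    option: int = 1,
) -> pd.DataFrame:
    """Vary the usual-care annual hospitalisation rate and report totals,
    QALYs and hospitalisations avoided per scenario."""
    rows = []
    for rate in annual_rates:
        if not (0.0 <= rate <= 1.0):
            raise ValidationError(f"hospitalisation rate must lie in [0,1], got {rate}")
        res = _run(_set_usual_hosp_annual(config, rate), jurisdiction, option)
        rows.append(
            {
                "usual_hospitalisation_rate_annual": rate,
                "total_cost_usual_aud": res.usual.total_cost,
                "total_cost_optimal_aud": res.optimal.total_cost,
                "delta_cost_aud": res.delta.delta_cost,
                "qalys_usual": res.usual.qalys,
                "qalys_optimal": res.optimal.qalys,
                "delta_qaly": res.delta.delta_qaly,
                "hospitalisations_avoided_events": res.hospitalisations_avoided,
            }
        )
    return pd.DataFrame(rows)


def scenario_prevalence(
    config: ModelConfig,
    prevalences: Sequence[float] = PREVALENCE_SCENARIOS,
    jurisdiction: str = AGGREGATE_NAME,
    option: int = 1,
) -> pd.DataFrame:
    """Vary the cycle-0 VLU prevalence and report totals per scenario."""
    rows = []
    for prev in prevalences:
        cfg = replace(
            config, settings=replace(config.settings, prevalence_at_cycle0=prev)
        )
        res = _run(cfg, jurisdiction, option)
        names = {j.name for j in config.jurisdictions}
        if jurisdiction in names:
            pops = [config.jurisdiction(jurisdiction).population_60plus]
        else:  # national run summed over the individual States/Territories
            pops = [
                j.population_60plus
                for j in config.jurisdictions
                if j.name != AGGREGATE_NAME
            ]
        affected0 = sum(round(prev * p) for p in pops)
        rows.append(
            {
                "prevalence_fraction": prev,
                "affected_at_cycle0_persons": affected0,
                "total_cost_usual_aud": res.usual.total_cost,
                "total_cost_optimal_aud": res.optimal.total_cost,
                "delta_cost_aud": res.delta.delta_cost,
                "qalys_usual": res.usual.qalys,
                "qalys_optimal": res.optimal.qalys,
                "delta_qaly": res.delta.delta_qaly,
                "hospitalisations_avoided_events": res.hospitalisations_avoided,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


_psa_shrink_logged = False


def _draw_beta(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Beta draw matched to (mean, cv*mean) by method of moments; the sd is
    shrunk to the feasible region if the requested moments are infeasible."""
    global _psa_shrink_logged
    if cv == 0.0 or mean in (0.0, 1.0):
        return mean
    sd = cv * mean
    max_sd = np.sqrt(mean * (1.0 - mean))
    if sd >= max_sd:
        if not _psa_shrink_logged:
            log.warning(
                "PSA sd %.4f infeasible for beta mean %.4f; shrinking to support",
                sd,
                mean,
            )
            _psa_shrink_logged = True
        sd = 0.95 * max_sd
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _draw_gamma(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Gamma draw matched to (mean, cv*mean) by method of moments."""
    if cv == 0.0 or mean == 0.0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean * cv**2))


def _sample_strategy(
    rng: np.random.Generator, s: StrategyParameters, cv: float
) -> StrategyParameters:
    def hp(p: HorizonProbability) -> HorizonProbability:
        return HorizonProbability(_draw_beta(rng, p.value, cv), p.horizon_cycles)

    return replace(
        s,
        p_heal=hp(s.p_heal),
        p_recur=hp(s.p_recur),
        p_hosp=hp(s.p_hosp),
        incidence=hp(s.incidence),
        mortality=hp(s.mortality),
        infection_share=_draw_beta(rng, s.infection_share, cv),
    )


def sample_psa_draw(
    config: ModelConfig, rng: np.random.Generator, cv: float | None = None
) -> ModelConfig:
    """One PSA parameter draw: betas for probabilities/utilities, gammas for
    unit costs, independent across parameters. Shared inputs (incidence,
    mortality) are drawn once and applied to both strategies."""
    if cv is None:
        cv = config.settings.psa_cv
    usual = _sample_strategy(rng, config.usual, cv)
    optimal = _sample_strategy(rng, config.optimal, cv)
    # Incidence and all-cause mortality are shared between arms.
    optimal = replace(optimal, incidence=usual.incidence, mortality=usual.mortality)

    u_unhealed = _draw_beta(rng, config.utilities.u_unhealed, cv)
    decrement = min(_draw_beta(rng, config.utilities.hosp_decrement, cv), u_unhealed)
    utilities = UtilitySet(
        u_healed=_draw_beta(rng, config.utilities.u_healed, cv),
        u_unhealed=u_unhealed,
        hosp_decrement=decrement,
    )

    cost_kwargs = {
        name: _draw_gamma(rng, value, cv)
        for name, value in config.unit_costs.__dict__.items()
        if name != "community_nurse_visit_hours"
    }
    unit_costs = UnitCosts(
        community_nurse_visit_hours=config.unit_costs.community_nurse_visit_hours,
        **cost_kwargs,
    )

    # Propagate the mortality draw to jurisdiction profiles as a relative
    # shift, preserving their baseline differences (identity at cv = 0).
    base_mort = config.usual.mortality.value
    factor = usual.mortality.value / base_mort if base_mort > 0 else 1.0
    jurisdictions = tuple(
        replace(
            j,
            mortality=HorizonProbability(
                min(1.0, j.mortality.value * factor), j.mortality.horizon_cycles
            ),
        )
        for j in config.jurisdictions
    )
    return replace(
        config,
        usual=usual,
        optimal=optimal,
        utilities=utilities,
        unit_costs=unit_costs,
        jurisdictions=jurisdictions,
    )


@dataclass(frozen=True)
class PSADraw:
    """Economic outcomes of one sampled parameter set."""

    index: int
    delta_cost: float
    delta_qaly: float
    nmb: float


@dataclass(frozen=True)
class CEACPoint:
    """One point of the cost-effectiveness acceptability curve."""

    wtp: float
    probability_cost_effective: float


@dataclass(frozen=True)
class PSAResult:
    draws: tuple[PSADraw, ...]
    ceac: tuple[CEACPoint, ...]
    wtp: float

    @property
    def probability_cost_effective(self) -> float:
        """Fraction of draws with NMB > 0 at the analysis willingness-to-pay."""
        return float(np.mean([d.nmb > 0 for d in self.draws]))

    @property
    def probability_cost_saving(self) -> float:
        """Fraction of draws in the dominant (southeast) quadrant."""
        return float(
            np.mean([(d.delta_cost < 0) and (d.delta_qaly > 0) for d in self.draws])
        )

    def plane_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": [d.index for d in self.draws],
                "delta_qaly": [d.delta_qaly for d in self.draws],
                "delta_cost_aud": [d.delta_cost for d in self.draws],
                "nmb_aud": [d.nmb for d in self.draws],
            }
        )

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp_aud_per_qaly": [c.wtp for c in self.ceac],
                "probability_cost_effective": [
                    c.probability_cost_effective for c in self.ceac
                ],
            }
        )


def run_psa(
    config: ModelConfig,
    n_iterations: int | None = None,
    seed: int | None = None,
    jurisdiction: str = AGGREGATE_NAME,
    option: int = 1,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the pipeline.

    Each iteration re-runs both strategy arms under one sampled parameter set
    and records (dC, dE, NMB); the CEAC reports, for each willingness-to-pay
    on the grid, the fraction of iterations with positive NMB.
    """
    if n_iterations is None:
        n_iterations = config.settings.psa_iterations
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    if seed is None:
        seed = config.settings.rng_seed
    rng = np.random.default_rng(seed)
    wtp = config.settings.wtp_aud_per_qaly

    draws = []
    dc = np.empty(n_iterations)
    de = np.empty(n_iterations)
    for i in range(n_iterations):
        cfg = sample_psa_draw(config, rng)
        res = _run(cfg, jurisdiction, option)
        dc[i] = res.delta.delta_cost
        de[i] = res.delta.delta_qaly
        draws.append(
            PSADraw(
                index=i,
                delta_cost=dc[i],
                delta_qaly=de[i],
                nmb=de[i] * wtp - dc[i],
            )
        )

    ceac = tuple(
        CEACPoint(
            wtp=float(lam),
            probability_cost_effective=float(np.mean(de * lam - dc > 0)),
        )
        for lam in wtp_grid
    )
    return PSAResult(draws=tuple(draws), ceac=ceac, wtp=wtp)


__all__ = [
    "CEACPoint",
    "DEFAULT_WTP_GRID",
    "DsaParameter",
    "HOSPITALISATION_SCENARIOS",
    "PREVALENCE_SCENARIOS",
    "PSADraw",
    "PSAResult",
    "TornadoEntry",
    "default_dsa_parameters",
    "one_way_dsa",
    "run_psa",
    "sample_psa_draw",
    "scenario_hospitalisation",
    "scenario_prevalence",
    "tornado_frame",
]
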