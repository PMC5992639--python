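"""End-to-end runs: cohort -> costing -> accrual -> incremental comparison."""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

from .cea import IncrementalResult, incremental
from .markov import CohortTrace, run_cohort
from .outcomes import EconResult, accrue, build_cost_schedule
from .parameters import AGGREGATE_NAME, JurisdictionProfile, ModelConfig


def run_strategy(
    config: ModelConfig,
    strategy_name: str,
    jurisdiction: JurisdictionProfile | str,
    option: int = 1,
) -> tuple[CohortTrace, EconResult]:
    """Run one strategy arm in one jurisdiction and accrue its economics."""
    if isinstance(jurisdiction, str):
        jurisdiction = config.jurisdiction(jurisdiction)
    strategy = config.strategy(strategy_name)
    trace = run_cohort(strategy, jurisdiction, config.settings)
    schedule = build_cost_schedule(
        config.unit_costs, strategy, jurisdiction, option, config.settings
    )
    return trace, accrue(trace, schedule, config.utilities, config.settings)


@dataclass(frozen=True)
class ComparisonResult:
    """Both arms plus their incremental comparison for one jurisdiction."""

    jurisdiction: str
    option: int
    usual: EconResult
    optimal: EconResult
    delta: IncrementalResult
    trace_usual: CohortTrace | None = None  # None for summed national results
    trace_optimal: CohortTrace | None = None

    @property
    def hospitalisations_avoided(self) -> float:
        return self.usual.hospitalisations - self.optimal.hospitalisations


def run_comparison(
    config: ModelConfig,
    jurisdiction: JurisdictionProfile | str,
    option: int = 1,
) -> ComparisonResult:
    if isinstance(jurisdiction, str):
        jurisdiction = config.jurisdiction(jurisdiction)
    trace_u, usual = run_strategy(config, "usual", jurisdiction, option)
    trace_o, optimal = run_strategy(config, "optimal", jurisdiction, option)
    return ComparisonResult(
        jurisdiction=jurisdiction.name,
        option=option,
        usual=usual,
        optimal=optimal,
        delta=incremental(optimal, usual),
        trace_usual=trace_u,
        trace_optimal=trace_o,
    )


def run_national(config: ModelConfig, option: int = 1) -> ComparisonResult:
    """Sum per-jurisdiction runs (each with its own payer shares, growth and
    mortality) into a national comparison. Skips any AGGREGATE profile so the
    national total is the sum of the eight States and Territories."""
    parts = [
        run_comparison(config, j, option)
        for j in config.jurisdictions
        if j.name != AGGREGATE_NAME
    ]
    if not parts:
        raise ValueError("no jurisdiction profiles to aggregate")
    usual = reduce(lambda a, b: a + b, (p.usual for p in parts))
    optimal = reduce(lambda a, b: a + b, (p.optimal for p in parts))
    return ComparisonResult(
        jurisdiction=AGGREGATE_NAME,
        option=option,
        usual=usual,
        optimal=optimal,
        delta=incremental(optimal, usual),
    )


__all__ = ["ComparisonResult", "run_comparison", "run_national", "run_strategy"]
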