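"""Incremental cost-effectiveness statistics for a pair of strategies."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .outcomes import CATEGORIES, PAYERS, EconResult
from .parameters import CostCategory, Payer, ValidationError

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental comparison of optimal vs usual care.

    ``icer`` is the cost per QALY gained; it is suppressed (``None``) in the
    dominance quadrants, where ``icer_class`` carries the label instead:
    "dominant" (cheaper and more effective) or "dominated" (dearer and less
    effective).
    """

    delta_cost: float  # AUD, optimal minus usual
    delta_qaly: float  # QALYs, optimal minus usual
    delta_cost_by_payer: dict[Payer, float]
    delta_cost_by_category: dict[CostCategory, float]

    @property
    def icer_class(self) -> str:
        if self.delta_cost < 0 and self.delta_qaly > 0:
            return DOMINANT
        if self.delta_cost > 0 and self.delta_qaly < 0:
            return DOMINATED
        return "ratio"

    @property
    def icer(self) -> float | None:
        if self.icer_class != "ratio":
            return None
        if self.delta_qaly == 0:
            return math.inf if self.delta_cost > 0 else 0.0
        return self.delta_cost / self.delta_qaly

    def nmb(self, wtp: float) -> float:
        """Net monetary benefit at willingness-to-pay ``wtp`` AUD/QALY:
        NMB = dE * lambda - dC."""
        if wtp < 0:
            raise ValidationError(f"willingness-to-pay must be >= 0, got {wtp!r}")
        return self.delta_qaly * wtp - self.delta_cost


def incremental(optimal: EconResult, usual: EconResult) -> IncrementalResult:
    """Differences (optimal minus usual), with payer and category breakdowns."""
    if optimal.jurisdiction != usual.jurisdiction:
        raise ValidationError(
            "incremental comparison requires results from the same jurisdiction, "
            f"got {optimal.jurisdiction!r} vs {usual.jurisdiction!r}"
        )
    return IncrementalResult(
        delta_cost=optimal.total_cost - usual.total_cost,
        delta_qaly=optimal.qalys - usual.qalys,
        delta_cost_by_payer={
            p: optimal.cost_by_payer(p) - usual.cost_by_payer(p) for p in PAYERS
        },
        delta_cost_by_category={
            c: optimal.cost_by_category(c) - usual.cost_by_category(c)
            for c in CATEGORIES
        },
    )


def net_monetary_benefit(delta: IncrementalResult, wtp: float) -> float:
    return delta.nmb(wtp)


def summary_frame(
    rows: list[tuple[str, int, EconResult, EconResult]], wtp: float
) -> pd.DataFrame:
    """One row per (jurisdiction, option): totals, deltas, ICER class, NMB."""
    out = []
    for jurisdiction, option, opt_res, usual_res in rows:
        inc = incremental(opt_res, usual_res)
        out.append(
            {
                "jurisdiction": jurisdiction,
                "option": option,
                "total_cost_usual_aud": usual_res.total_cost,
                "total_cost_optimal_aud": opt_res.total_cost,
                "delta_cost_aud": inc.delta_cost,
                "qalys_usual": usual_res.qalys,
                "qalys_optimal": opt_res.qalys,
                "delta_qaly": inc.delta_qaly,
                "icer_class": inc.icer_class,
                "icer_aud_per_qaly": inc.icer,
                "nmb_aud": inc.nmb(wtp),
                "hospitalisations_avoided_events": (
                    usual_res.hospitalisations - opt_res.hospitalisations
                ),
            }
        )
    return pd.DataFrame(out)


__all__ = [
    "DOMINANT",
    "DOMINATED",
    "IncrementalResult",
    "incremental",
    "net_monetary_benefit",
    "summary_frame",
]
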