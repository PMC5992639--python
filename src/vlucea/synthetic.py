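"""Synthetic jurisdiction profiles: stand-ins for unpublished State-level inputs.

The national analysis needs, for each of the eight Australian States and
Territories, the population aged 60+, its per-fortnight growth, all-cause
mortality and the payer split of each cost category. Those inputs are not
publicly deposited, so this module generates plausible synthetic profiles:

* populations are drawn around the real relative sizes of the States and
  rescaled to sum exactly to the national 60+ total (default 4,840,400, the
  unique value consistent with a 1% prevalence giving 48,404 affected
  persons at cycle 0);
* growth reflects the ~3%/year expansion of the 60+ age group in the 2010s;
* payer-share archetypes encode the known funding quirks: ACT-like profiles
  fully subsidise consumables (zero out-of-pocket dressings), QLD/VIC-like
  profiles leave a high out-of-pocket consumables share.

All profiles are deterministic given the seed and labelled synthetic; they
support qualitative national conclusions (dominance, monotonicity), not
exact State-level cost totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    AGGREGATE_NAME,
    AnalysisSettings,
    CYCLES_PER_YEAR,
    CostCategory,
    HOSPITAL_PAYER_SHARES,
    HorizonProbability,
    JURISDICTION_NAMES,
    JurisdictionProfile,
    ModelConfig,
    PayerShares,
    ProviderMix,
    UnitCosts,
    UtilitySet,
    baseline_strategies,
)

#: National population aged 60+ (persons); 48,404 / 0.01.
NATIONAL_POPULATION_60PLUS = 4_840_400

# Approximate relative sizes of the 60+ populations by State/Territory.
_BASE_SHARES = {
    "NSW": 0.320,
    "VIC": 0.250,
    "QLD": 0.200,
    "SA": 0.080,
    "WA": 0.095,
    "NT": 0.006,
    "TAS": 0.027,
    "ACT": 0.022,
}

# Out-of-pocket share of the consumables (dressings) category per archetype.
_HIGH_OOP = {"QLD", "VIC"}
_ZERO_OOP = {"ACT"}


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Controls for the synthetic jurisdiction generator."""

    national_population_60plus: int = NATIONAL_POPULATION_60PLUS
    share_dispersion: float = 0.03  # relative jitter on population shares
    annual_growth_range: tuple[float, float] = (0.025, 0.035)
    mortality_annual_range: tuple[float, float] = (0.0254, 0.0310)
    seed: int = 0


def _payer_shares_for(name: str, rng: np.random.Generator) -> dict[CostCategory, PayerShares]:
    if name in _ZERO_OOP:
        dressings_oop = 0.0
    elif name in _HIGH_OOP:
        dressings_oop = float(rng.uniform(0.6, 0.8))
    else:
        dressings_oop = float(rng.uniform(0.35, 0.55))
    # Consumables not paid by patients are funded by the States (community
    # nursing / outpatient supplies).
    dressings = PayerShares(0.0, 1.0 - dressings_oop, dressings_oop)
    services_oop = float(rng.uniform(0.10, 0.20))
    services = PayerShares(1.0 - services_oop, 0.0, services_oop)
    medicines_oop = float(rng.uniform(0.15, 0.25))
    medicines = PayerShares(1.0 - medicines_oop, 0.0, medicines_oop)
    # Compression shares are overridden per strategy at costing time; the
    # profile still carries a valid placeholder split.
    compression = PayerShares(0.0, 0.0, 1.0)
    return {
        CostCategory.COMPRESSION: compression,
        CostCategory.DRESSINGS: dressings,
        CostCategory.SERVICES: services,
        CostCategory.MEDICINES: medicines,
        CostCategory.HOSPITAL: HOSPITAL_PAYER_SHARES,
    }


def generate_jurisdictions(
    spec: SyntheticProfileSpec | None = None,
) -> list[JurisdictionProfile]:
    """Generate the eight State/Territory profiles plus a national AGGREGATE.

    Populations are jittered around the base shares and rescaled so the eight
    States sum exactly to the national total; the AGGREGATE profile carries
    the national population, the summed growth inflow, and population-weighted
    mortality, payer shares and provider mix.
    """
    spec = spec or SyntheticProfileSpec()
    rng = np.random.default_rng(spec.seed)

    shares = np.array([_BASE_SHARES[n] for n in JURISDICTION_NAMES])
    shares = shares * (1.0 + spec.share_dispersion * rng.standard_normal(len(shares)))
    shares = np.clip(shares, 1e-4, None)
    shares /= shares.sum()
    pops = np.floor(shares * spec.national_population_60plus).astype(int)
    pops[0] += spec.national_population_60plus - pops.sum()  # exact national sum

    profiles: list[JurisdictionProfile] = []
    for name, pop in zip(JURISDICTION_NAMES, pops):
        growth_annual = float(rng.uniform(*spec.annual_growth_range))
        mortality_annual = float(rng.uniform(*spec.mortality_annual_range))
        mix = rng.dirichlet(np.array([0.4, 0.4, 0.2]) * 60.0)
        profiles.append(
            JurisdictionProfile(
                name=name,
                population_60plus=float(pop),
                growth_per_cycle=float(pop) * growth_annual / CYCLES_PER_YEAR,
                mortality=HorizonProbability(mortality_annual, CYCLES_PER_YEAR),
                payer_shares=_payer_shares_for(name, rng),
                provider_mix=ProviderMix(*map(float, mix)),
            )
        )

    profiles.append(_aggregate_profile(profiles))
    return profiles


def _aggregate_profile(profiles: list[JurisdictionProfile]) -> JurisdictionProfile:
    pops = np.array([p.population_60plus for p in profiles])
    w = pops / pops.sum()

    def wavg(values: list[float]) -> float:
        return float(np.dot(w, values))

    shares: dict[CostCategory, PayerShares] = {}
    for cat in CostCategory:
        triple = [
            wavg([getattr(p.payer_shares[cat], field) for p in profiles])
            for field in ("australian_govt", "state_govt", "out_of_pocket")
        ]
        total = sum(triple)
        shares[cat] = PayerShares(*(x / total for x in triple))
    mix = [
        wavg([getattr(p.provider_mix, field) for p in profiles])
        for field in ("gp", "community_nurse", "outpatient_clinic")
    ]
    mix_total = sum(mix)
    return JurisdictionProfile(
        name=AGGREGATE_NAME,
        population_60plus=float(pops.sum()),
        growth_per_cycle=float(sum(p.growth_per_cycle for p in profiles)),
        mortality=HorizonProbability(
            wavg([p.mortality.value for p in profiles]), CYCLES_PER_YEAR
        ),
        payer_shares=shares,
        provider_mix=ProviderMix(*(x / mix_total for x in mix)),
    )


def generate_baseline_bundle(seed: int = 0) -> ModelConfig:
    """The standard integration fixture: published baseline strategy, utility
    and unit-cost inputs combined with synthetic jurisdiction profiles."""
    usual, optimal = baseline_strategies()
    return ModelConfig(
        usual=usual,
        optimal=optimal,
        utilities=UtilitySet(),
        unit_costs=UnitCosts(),
        jurisdictions=tuple(generate_jurisdictions(SyntheticProfileSpec(seed=seed))),
        settings=AnalysisSettings(rng_seed=seed),
    )


__all__ = [
    "NATIONAL_POPULATION_60PLUS",
    "SyntheticProfileSpec",
    "generate_jurisdictions",
    "generate_baseline_bundle",
]
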