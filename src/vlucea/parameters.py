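"""Model parameters: domain types, validation, probability conversion, config I/O.

All inputs of the venous-leg-ulcer (VLU) Markov model live here: per-strategy
transition probabilities (each tagged with the time horizon it natively spans),
quality-of-life utilities, unit costs (AUD, 2015 prices), jurisdiction profiles
(population aged 60+, per-cycle growth, payer cost-share fractions) and the
analysis settings (cycle structure, discounting, willingness-to-pay, PSA/DSA
controls).

The model runs on fortnightly cycles: 6.5 cycles = 3 months, 26 cycles = 1
year, 130 cycles = 5 years.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

log = logging.getLogger(__name__)

# Fortnightly cycle structure.
CYCLES_PER_QUARTER = 6.5
CYCLES_PER_YEAR = 26.0
CYCLES_PER_FIVE_YEARS = 130.0

JURISDICTION_NAMES = ("NSW", "VIC", "QLD", "SA", "WA", "NT", "TAS", "ACT")
AGGREGATE_NAME = "AGGREGATE"


class ValidationError(ValueError):
    """A model input violates its domain (range, sum, schema)."""


class HealthState(enum.IntEnum):
    """The five mutually exclusive health states. DEAD is absorbing."""

    NO_VLU = 0
    UNHEALED = 1
    HEALED = 2
    HOSPITALISED = 3
    DEAD = 4


N_STATES = len(HealthState)

#: States whose occupants have ever had a VLU and therefore accrue costs/QALYs.
AFFECTED_STATES = (HealthState.UNHEALED, HealthState.HEALED, HealthState.HOSPITALISED)


class CostCategory(enum.Enum):
    """Cost categories used for payer decomposition of totals."""

    COMPRESSION = "compression"
    DRESSINGS = "dressings"
    SERVICES = "services"
    HOSPITAL = "hospital"
    MEDICINES = "medicines"


class Payer(enum.Enum):
    """Who pays: federal government (MBS/PBS), state government, or the patient."""

    AUSTRALIAN_GOVT = "australian_govt"
    STATE_GOVT = "state_govt"
    OUT_OF_POCKET = "out_of_pocket"


def _check_fraction(name: str, x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {x!r}")


@dataclass(frozen=True)
class HorizonProbability:
    """A probability together with the number of fortnightly cycles it spans.

    Literature probabilities arrive on mixed horizons (3-month healing, annual
    recurrence, 5-year hospitalisation); each is stored with its native horizon
    and converted to a per-cycle probability only where the transition matrix
    is assembled.
    """

    value: float
    horizon_cycles: float = 1.0

    def __post_init__(self) -> None:
        _check_fraction("probability value", self.value)
        if not self.horizon_cycles > 0:
            raise ValidationError(
                f"horizon_cycles must be positive, got {self.horizon_cycles!r}"
            )

    @property
    def per_cycle(self) -> float:
        return to_per_cycle(self)


def to_per_cycle(p: HorizonProbability) -> float:
    """Convert a probability spanning ``horizon_cycles`` fortnights to one fortnight.

    Uses the constant-hazard transformation tp = 1 - (1 - tp_t)^(1/t): the
    complement survives each of the t sub-intervals independently.
    """
    if p.horizon_cycles <= 0:
        raise ValidationError("horizon_cycles must be positive")
    return 1.0 - (1.0 - p.value) ** (1.0 / p.horizon_cycles)


def compose_cycles(p_cycle: float, n: float) -> float:
    """Probability of at least one event over ``n`` cycles at per-cycle risk ``p_cycle``.

    Exact algebraic inverse of :func:`to_per_cycle`:
    ``compose_cycles(to_per_cycle(p), p.horizon_cycles) == p.value``.
    """
    _check_fraction("per-cycle probability", p_cycle)
    if n <= 0:
        raise ValidationError(f"cycle count must be positive, got {n!r}")
    return 1.0 - (1.0 - p_cycle) ** n


@dataclass(frozen=True)
class StrategyParameters:
    """Transition and infection inputs for one system of care.

    ``p_hosp`` natively spans 5 years under usual care (0.24) but 1 year under
    optimal care (0.0116); the mixed horizons are reconciled per cycle by
    :func:`to_per_cycle`. ``compression_coverage`` is the fraction of unhealed
    patients prescribed high compression (0.5 usual, 1.0 optimal) and scales
    the compression-product spend, not the healing probability (the healing
    rates were observed under the corresponding coverage levels).
    """

    name: str
    p_heal: HorizonProbability
    p_recur: HorizonProbability
    p_hosp: HorizonProbability
    incidence: HorizonProbability
    mortality: HorizonProbability
    infection_share: float
    compression_coverage: float

    def __post_init__(self) -> None:
        _check_fraction("infection_share", self.infection_share)
        _check_fraction("compression_coverage", self.compression_coverage)


@dataclass(frozen=True)
class UtilitySet:
    """Annual quality-of-life utility weights per health state.

    The hospitalised utility is defined as the unhealed utility minus a fixed
    decrement (baseline 0.64 - 0.1 = 0.54).
    """

    u_healed: float = 0.75
    u_unhealed: float = 0.64
    hosp_decrement: float = 0.1

    def __post_init__(self) -> None:
        _check_fraction("u_healed", self.u_healed)
        _check_fraction("u_unhealed", self.u_unhealed)
        _check_fraction("u_hospitalised", self.u_unhealed - self.hosp_decrement)

    @property
    def u_hospitalised(self) -> float:
        return self.u_unhealed - self.hosp_decrement

    def for_state(self, state: HealthState) -> float:
        if state is HealthState.UNHEALED:
            return self.u_unhealed
        if state is HealthState.HEALED:
            return self.u_healed
        if state is HealthState.HOSPITALISED:
            return self.u_hospitalised
        return 0.0


# Unit costs the source tables do not print; shipped defaults are assumptions
# and a notice is logged whenever they are filled in.
_ASSUMED_COST_DEFAULTS = {
    "dressing_change_aud": 15.0,
    "antibiotics_course_aud": 25.0,
    "debridement_session_aud": 40.0,
    "outpatient_clinic_visit_aud": 58.55,
}


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs in 2015 Australian dollars.

    Printed items default to their scheduled (MBS) or retail values. The last
    four (dressing consumable per change, systemic-antibiotic course,
    debridement session, outpatient-clinic visit) are not printed anywhere and
    are config-supplied assumptions.
    """

    gp_consult_aud: float = 71.70
    nurse_practitioner_consult_aud: float = 58.55
    vascular_surgeon_consult_aud: float = 85.55
    community_nurse_hour_aud: float = 30.90  # midpoint of the 24.74-37.05 wage range
    community_nurse_visit_hours: float = 1.0
    abpi_assessment_aud: float = 63.74
    pathology_test_aud: float = 33.75
    compression_bandage_aud: float = 51.50
    compression_stocking_aud: float = 97.75
    hospitalisation_aud: float = 18331.60
    dressing_change_aud: float = _ASSUMED_COST_DEFAULTS["dressing_change_aud"]
    antibiotics_course_aud: float = _ASSUMED_COST_DEFAULTS["antibiotics_course_aud"]
    debridement_session_aud: float = _ASSUMED_COST_DEFAULTS["debridement_session_aud"]
    outpatient_clinic_visit_aud: float = _ASSUMED_COST_DEFAULTS[
        "outpatient_clinic_visit_aud"
    ]

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValidationError(f"unit cost {name} must be >= 0, got {value!r}")

    @property
    def community_nurse_visit_aud(self) -> float:
        return self.community_nurse_hour_aud * self.community_nurse_visit_hours


@dataclass(frozen=True)
class PayerShares:
    """Fractions of one cost category borne by each payer; must sum to 1."""

    australian_govt: float
    state_govt: float
    out_of_pocket: float

    def __post_init__(self) -> None:
        for payer in Payer:
            _check_fraction(f"payer share {payer.value}", getattr(self, payer.value))
        total = self.australian_govt + self.state_govt + self.out_of_pocket
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"payer shares must sum to 1, got {total!r}")

    def __getitem__(self, payer: Payer) -> float:
        return getattr(self, payer.value)

    def as_dict(self) -> dict[Payer, float]:
        return {p: self[p] for p in Payer}


#: Public hospitals are funded 60% by State/Territory and 40% federally.
HOSPITAL_PAYER_SHARES = PayerShares(
    australian_govt=0.40, state_govt=0.60, out_of_pocket=0.0
)


@dataclass(frozen=True)
class ProviderMix:
    """Fractions of Option-2 clinic visits delivered by each provider type."""

    gp: float
    community_nurse: float
    outpatient_clinic: float

    def __post_init__(self) -> None:
        for name in ("gp", "community_nurse", "outpatient_clinic"):
            _check_fraction(f"provider mix {name}", getattr(self, name))
        total = self.gp + self.community_nurse + self.outpatient_clinic
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"provider mix must sum to 1, got {total!r}")


DEFAULT_PROVIDER_MIX = ProviderMix(gp=0.4, community_nurse=0.4, outpatient_clinic=0.2)


@dataclass(frozen=True)
class JurisdictionProfile:
    """One State/Territory (or the national aggregate): population, growth,
    mortality and the payer split of each cost category."""

    name: str
    population_60plus: float
    growth_per_cycle: float
    mortality: HorizonProbability
    payer_shares: Mapping[CostCategory, PayerShares]
    provider_mix: ProviderMix = DEFAULT_PROVIDER_MIX

    def __post_init__(self) -> None:
        valid = JURISDICTION_NAMES + (AGGREGATE_NAME,)
        if self.name not in valid:
            raise ValidationError(
                f"unknown jurisdiction {self.name!r}; expected one of {valid}"
            )
        if self.population_60plus < 0:
            raise ValidationError("population_60plus must be >= 0")
        if self.growth_per_cycle < 0:
            raise ValidationError("growth_per_cycle must be >= 0")
        missing = [c for c in CostCategory if c not in self.payer_shares]
        if missing:
            raise ValidationError(
                f"jurisdiction {self.name}: missing payer shares for {missing}"
            )


def default_payer_shares() -> dict[CostCategory, PayerShares]:
    """Payer splits used when a jurisdiction profile does not specify them.

    Services and medicines are MBS/PBS-reimbursed with a patient co-payment;
    consumables are largely patient-paid under usual arrangements; hospital
    funding is the fixed 60/40 State/federal split.
    """
    return {
        CostCategory.COMPRESSION: PayerShares(0.0, 0.0, 1.0),
        CostCategory.DRESSINGS: PayerShares(0.5, 0.0, 0.5),
        CostCategory.SERVICES: PayerShares(0.85, 0.0, 0.15),
        CostCategory.MEDICINES: PayerShares(0.8, 0.0, 0.2),
        CostCategory.HOSPITAL: HOSPITAL_PAYER_SHARES,
    }


@dataclass(frozen=True)
class AnalysisSettings:
    """Run controls: horizon, discounting, WTP, PSA/DSA settings and the
    structural switches that the source description leaves open."""

    n_cycles: int = 130
    cycle_length_years: float = 1.0 / 26.0
    discount_rate_per_year: float = 0.05
    wtp_aud_per_qaly: float = 64000.0
    prevalence_at_cycle0: float = 0.0033
    psa_iterations: int = 10000
    psa_cv: float = 0.2
    dsa_rel_range: float = 0.2
    rng_seed: int = 0
    # Structural switches (defaults documented in the methods note).
    discharge_destination: str = "unhealed"  # or "healed"
    half_cycle_correction: bool = False
    entry_cost_on_discharge: bool = False
    bandages_per_dressing_change: float = 1.0
    usual_compression_govt_share: float = 0.556

    def __post_init__(self) -> None:
        if self.n_cycles < 0:
            raise ValidationError("n_cycles must be >= 0")
        if self.discount_rate_per_year < 0:
            raise ValidationError("discount_rate_per_year must be >= 0")
        if self.wtp_aud_per_qaly <= 0:
            raise ValidationError("wtp_aud_per_qaly must be > 0")
        _check_fraction("prevalence_at_cycle0", self.prevalence_at_cycle0)
        _check_fraction("usual_compression_govt_share", self.usual_compression_govt_share)
        if self.psa_cv < 0:
            raise ValidationError("psa_cv must be >= 0")
        if self.discharge_destination not in ("unhealed", "healed"):
            raise ValidationError(
                "discharge_destination must be 'unhealed' or 'healed', "
                f"got {self.discharge_destination!r}"
            )


@dataclass(frozen=True)
class ModelConfig:
    """The full validated parameter bundle consumed by every pipeline stage."""

    usual: StrategyParameters
    optimal: StrategyParameters
    utilities: UtilitySet
    unit_costs: UnitCosts
    jurisdictions: tuple[JurisdictionProfile, ...]
    settings: AnalysisSettings

    def jurisdiction(self, name: str) -> JurisdictionProfile:
        for j in self.jurisdictions:
            if j.name == name:
                return j
        known = [j.name for j in self.jurisdictions]
        raise ValidationError(f"unknown jurisdiction {name!r}; have {known}")

    def strategy(self, name: str) -> StrategyParameters:
        if name == "usual":
            return self.usual
        if name == "optimal":
            return self.optimal
        raise ValidationError(f"unknown strategy {name!r}; expected usual|optimal")


def baseline_strategies() -> tuple[StrategyParameters, StrategyParameters]:
    """The published baseline usual-care and optimal-care parameter sets."""
    incidence = HorizonProbability(0.0121, CYCLES_PER_YEAR)
    mortality = HorizonProbability(0.0282, CYCLES_PER_YEAR)
    usual = StrategyParameters(
        name="usual",
        p_heal=HorizonProbability(0.2281, CYCLES_PER_QUARTER),
        p_recur=HorizonProbability(0.5574, CYCLES_PER_YEAR),
        p_hosp=HorizonProbability(0.24, CYCLES_PER_FIVE_YEARS),
        incidence=incidence,
        mortality=mortality,
        infection_share=0.10,
        compression_coverage=0.5,
    )
    optimal = StrategyParameters(
        name="optimal",
        p_heal=HorizonProbability(0.5872, CYCLES_PER_QUARTER),
        p_recur=HorizonProbability(0.2222, CYCLES_PER_YEAR),
        p_hosp=HorizonProbability(0.0116, CYCLES_PER_YEAR),
        incidence=incidence,
        mortality=mortality,
        infection_share=0.05,
        compression_coverage=1.0,
    )
    return usual, optimal


# ---------------------------------------------------------------------------
# Config serialization (YAML with explicit units in key names)
# ---------------------------------------------------------------------------


def _hp_to_dict(p: HorizonProbability) -> dict[str, float]:
    return {"probability": p.value, "horizon_cycles": p.horizon_cycles}


def _hp_from_dict(d: Mapping[str, Any], where: str) -> HorizonProbability:
    _reject_unknown(d, {"probability", "horizon_cycles"}, where)
    try:
        return HorizonProbability(
            float(d["probability"]), float(d.get("horizon_cycles", 1.0))
        )
    except KeyError as e:
        raise ValidationError(f"{where}: missing key {e.args[0]!r}") from None


def _reject_unknown(d: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"{where}: unknown keys {sorted(unknown)}")


_STRATEGY_KEYS = {
    "p_heal",
    "p_recur",
    "p_hosp",
    "incidence",
    "mortality",
    "infection_share_fraction",
    "compression_coverage_fraction",
}


def _strategy_to_dict(s: StrategyParameters) -> dict[str, Any]:
    return {
        "p_heal": _hp_to_dict(s.p_heal),
        "p_recur": _hp_to_dict(s.p_recur),
        "p_hosp": _hp_to_dict(s.p_hosp),
        "incidence": _hp_to_dict(s.incidence),
        "mortality": _hp_to_dict(s.mortality),
        "infection_share_fraction": s.infection_share,
        "compression_coverage_fraction": s.compression_coverage,
    }


def _strategy_from_dict(name: str, d: Mapping[str, Any]) -> StrategyParameters:
    where = f"strategies.{name}"
    _reject_unknown(d, _STRATEGY_KEYS, where)
    try:
        return StrategyParameters(
            name=name,
            p_heal=_hp_from_dict(d["p_heal"], f"{where}.p_heal"),
            p_recur=_hp_from_dict(d["p_recur"], f"{where}.p_recur"),
            p_hosp=_hp_from_dict(d["p_hosp"], f"{where}.p_hosp"),
            incidence=_hp_from_dict(d["incidence"], f"{where}.incidence"),
            mortality=_hp_from_dict(d["mortality"], f"{where}.mortality"),
            infection_share=float(d["infection_share_fraction"]),
            compression_coverage=float(d["compression_coverage_fraction"]),
        )
    except KeyError as e:
        raise ValidationError(f"{where}: missing key {e.args[0]!r}") from None


def _jurisdiction_to_dict(j: JurisdictionProfile) -> dict[str, Any]:
    return {
        "name": j.name,
        "population_60plus_persons": j.population_60plus,
        "growth_per_cycle_persons": j.growth_per_cycle,
        "mortality": _hp_to_dict(j.mortality),
        "payer_shares_fraction": {
            cat.value: {p.value: j.payer_shares[cat][p] for p in Payer}
            for cat in CostCategory
        },
        "provider_mix_fraction": {
            "gp": j.provider_mix.gp,
            "community_nurse": j.provider_mix.community_nurse,
            "outpatient_clinic": j.provider_mix.outpatient_clinic,
        },
    }


def _jurisdiction_from_dict(d: Mapping[str, Any]) -> JurisdictionProfile:
    where = f"jurisdictions[{d.get('name', '?')}]"
    _reject_unknown(
        d,
        {
            "name",
            "population_60plus_persons",
            "growth_per_cycle_persons",
            "mortality",
            "payer_shares_fraction",
            "provider_mix_fraction",
        },
        where,
    )
    try:
        shares_raw = d["payer_shares_fraction"]
        shares: dict[CostCategory, PayerShares] = {}
        for cat in CostCategory:
            if cat.value not in shares_raw:
                raise ValidationError(f"{where}: missing payer shares for {cat.value}")
            t = shares_raw[cat.value]
            _reject_unknown(t, {p.value for p in Payer}, f"{where}.{cat.value}")
            shares[cat] = PayerShares(**{k: float(v) for k, v in t.items()})
        mix_raw = d.get("provider_mix_fraction")
        mix = (
            ProviderMix(**{k: float(v) for k, v in mix_raw.items()})
            if mix_raw
            else DEFAULT_PROVIDER_MIX
        )
        return JurisdictionProfile(
            name=str(d["name"]),
            population_60plus=float(d["population_60plus_persons"]),
            growth_per_cycle=float(d["growth_per_cycle_persons"]),
            mortality=_hp_from_dict(d["mortality"], f"{where}.mortality"),
            payer_shares=shares,
            provider_mix=mix,
        )
    except KeyError as e:
        raise ValidationError(f"{where}: missing key {e.args[0]!r}") from None


_SETTINGS_KEYS = {
    "n_cycles",
    "discount_rate_per_year",
    "wtp_aud_per_qaly",
    "prevalence_at_cycle0_fraction",
    "psa_iterations",
    "psa_cv",
    "dsa_rel_range",
    "rng_seed",
    "discharge_destination",
    "half_cycle_correction",
    "entry_cost_on_discharge",
    "bandages_per_dressing_change",
    "usual_compression_govt_share_fraction",
}


def _settings_to_dict(s: AnalysisSettings) -> dict[str, Any]:
    return {
        "n_cycles": s.n_cycles,
        "discount_rate_per_year": s.discount_rate_per_year,
        "wtp_aud_per_qaly": s.wtp_aud_per_qaly,
        "prevalence_at_cycle0_fraction": s.prevalence_at_cycle0,
        "psa_iterations": s.psa_iterations,
        "psa_cv": s.psa_cv,
        "dsa_rel_range": s.dsa_rel_range,
        "rng_seed": s.rng_seed,
        "discharge_destination": s.discharge_destination,
        "half_cycle_correction": s.half_cycle_correction,
        "entry_cost_on_discharge": s.entry_cost_on_discharge,
        "bandages_per_dressing_change": s.bandages_per_dressing_change,
        "usual_compression_govt_share_fraction": s.usual_compression_govt_share,
    }


def _settings_from_dict(d: Mapping[str, Any]) -> AnalysisSettings:
    _reject_unknown(d, _SETTINGS_KEYS, "settings")
    kwargs: dict[str, Any] = {}
    mapping = {
        "n_cycles": ("n_cycles", int),
        "discount_rate_per_year": ("discount_rate_per_year", float),
        "wtp_aud_per_qaly": ("wtp_aud_per_qaly", float),
        "prevalence_at_cycle0_fraction": ("prevalence_at_cycle0", float),
        "psa_iterations": ("psa_iterations", int),
        "psa_cv": ("psa_cv", float),
        "dsa_rel_range": ("dsa_rel_range", float),
        "rng_seed": ("rng_seed", int),
        "discharge_destination": ("discharge_destination", str),
        "half_cycle_correction": ("half_cycle_correction", bool),
        "entry_cost_on_discharge": ("entry_cost_on_discharge", bool),
        "bandages_per_dressing_change": ("bandages_per_dressing_change", float),
        "usual_compression_govt_share_fraction": ("usual_compression_govt_share", float),
    }
    for key, (attr, conv) in mapping.items():
        if key in d:
            kwargs[attr] = conv(d[key])
    return AnalysisSettings(**kwargs)


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    return {
        "strategies": {
            "usual": _strategy_to_dict(config.usual),
            "optimal": _strategy_to_dict(config.optimal),
        },
        "utilities_per_year": {
            "healed": config.utilities.u_healed,
            "unhealed": config.utilities.u_unhealed,
            "hospitalisation_decrement": config.utilities.hosp_decrement,
        },
        "unit_costs_aud": {
            k: v for k, v in config.unit_costs.__dict__.items()
        },
        "jurisdictions": [_jurisdiction_to_dict(j) for j in config.jurisdictions],
        "settings": _settings_to_dict(config.settings),
    }


def config_from_dict(raw: Mapping[str, Any]) -> ModelConfig:
    _reject_unknown(
        raw,
        {"strategies", "utilities_per_year", "unit_costs_aud", "jurisdictions", "settings"},
        "config",
    )
    strat_raw = raw.get("strategies")
    if not strat_raw:
        raise ValidationError("config: missing 'strategies' section")
    _reject_unknown(strat_raw, {"usual", "optimal"}, "strategies")
    for key in ("usual", "optimal"):
        if key not in strat_raw:
            raise ValidationError(f"strategies: missing {key!r}")

    util_raw = raw.get("utilities_per_year", {})
    _reject_unknown(
        util_raw, {"healed", "unhealed", "hospitalisation_decrement"}, "utilities_per_year"
    )
    utilities = UtilitySet(
        u_healed=float(util_raw.get("healed", 0.75)),
        u_unhealed=float(util_raw.get("unhealed", 0.64)),
        hosp_decrement=float(util_raw.get("hospitalisation_decrement", 0.1)),
    )

    cost_raw = dict(raw.get("unit_costs_aud", {}))
    allowed_costs = set(UnitCosts().__dict__)
    _reject_unknown(cost_raw, allowed_costs, "unit_costs_aud")
    for name, default in _ASSUMED_COST_DEFAULTS.items():
        if name not in cost_raw:
            log.warning(
                "unit cost %s not supplied; using assumed default %.2f AUD", name, default
            )
    unit_costs = UnitCosts(**{k: float(v) for k, v in cost_raw.items()})

    jur_raw = raw.get("jurisdictions", [])
    jurisdictions = tuple(_jurisdiction_from_dict(j) for j in jur_raw)
    if not jurisdictions:
        raise ValidationError("config: at least one jurisdiction is required")

    settings = _settings_from_dict(raw.get("settings", {}))

    return ModelConfig(
        usual=_strategy_from_dict("usual", strat_raw["usual"]),
        optimal=_strategy_from_dict("optimal", strat_raw["optimal"]),
        utilities=utilities,
        unit_costs=unit_costs,
        jurisdictions=jurisdictions,
        settings=settings,
    )


def packaged_baseline_path() -> Path:
    """Path to the shipped baseline config: published baseline inputs plus
    synthetic jurisdiction profiles (labelled synthetic in the filename)."""
    return Path(__file__).parent / "data" / "baseline_synthetic.yaml"


def load_model_config(path: str | Path) -> ModelConfig:
    """Load and validate a full parameter bundle from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValidationError(f"{path}: config must be a mapping at top level")
    return config_from_dict(raw)


def save_model_config(config: ModelConfig, path: str | Path) -> None:
    """Write a bundle back to YAML; load -> save -> load is the identity."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


__all__ = [
    "AFFECTED_STATES",
    "AGGREGATE_NAME",
    "AnalysisSettings",
    "CostCategory",
    "CYCLES_PER_FIVE_YEARS",
    "CYCLES_PER_QUARTER",
    "CYCLES_PER_YEAR",
    "DEFAULT_PROVIDER_MIX",
    "HOSPITAL_PAYER_SHARES",
    "HealthState",
    "HorizonProbability",
    "JURISDICTION_NAMES",
    "JurisdictionProfile",
    "ModelConfig",
    "N_STATES",
    "Payer",
    "PayerShares",
    "ProviderMix",
    "StrategyParameters",
    "UnitCosts",
    "UtilitySet",
    "ValidationError",
    "baseline_strategies",
    "compose_cycles",
    "config_from_dict",
    "config_to_dict",
    "default_payer_shares",
    "load_model_config",
    "packaged_baseline_path",
    "save_model_config",
    "to_per_cycle",
]
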