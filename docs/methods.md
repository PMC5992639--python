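# Methods

## Model structure

The model is a discrete-time Markov cohort simulation of the Australian
population aged 60 and over, run on fortnightly cycles (1/26 of a year) for
130 cycles. Horizon constants are fixed once: 3 months = 6.5 cycles,
1 year = 26 cycles, 5 years = 130 cycles. Five states: No VLU, Unhealed
VLU, Healed, Complicated VLU with hospitalisation, Death (absorbing).
Structural zeros encode the care pathway: nobody moves from No VLU straight
to Healed or hospital; healed patients can only recur or die; the state
diagram has no edge back to No VLU, so "No VLU" occupancy is exactly the
never-affected susceptible pool. Hospital stays last one cycle; survivors
are discharged to Unhealed by default (treating a complication does not
heal the ulcer) — a config switch (`discharge_destination: healed`) exposes
the alternative so its influence can be tested.

At cycle 0 a prevalence fraction (default 0.33%) of the jurisdiction's 60+
population starts in Unhealed (rounded to whole persons); the rest start
susceptible. Each cycle, transitions are applied first and the population
growth inflow (people turning 60) is then added to the susceptible pool, so
inflow is not exposed to the mortality of the cycle in which it arrives.
Fractional persons are carried throughout (cohort expectation); rounding
happens only at initialisation.

Competing exits from a state are the independently converted per-cycle
probabilities, summed, with the stay probability as the complement. No
cause-elimination adjustment is applied; if converted exits sum above 1 the
inputs are rejected rather than renormalised, since silent renormalisation
would hide an inconsistent parameter set.

### Probability conversion

All native-horizon probabilities are converted with
`tp = 1 − (1 − tp_t)^(1/t)` (constant hazard within the horizon), and the
inverse composition `1 − (1 − tp)^n` restates per-cycle values on any other
horizon. The conversion is exact round-trip to 1e-12, which the property
suite checks over random draws. Whether the original spreadsheet used 6.5
or 6 cycles for "3 months" cannot be determined from the published
material; the horizon is part of the config (`horizon_cycles`), so either
convention is reproducible. We use 6.5 (= 26/4).

## Baseline parameters

Transition inputs (usual / optimal): 3-month healing 0.2281 / 0.5872;
annual recurrence 0.5574 / 0.2222; hospitalisation 0.24 over 5 years /
0.0116 per year; shared annual incidence 0.0121 and all-cause mortality
0.0282; infected share of unhealed person-cycles 10% / 5%; compression
coverage 50% / 100%. Utilities per year: healed 0.75, unhealed 0.64,
hospitalised 0.64 − 0.1 = 0.54. Unit costs (2015 AUD): GP 71.70, nurse
practitioner 58.55, vascular surgeon 85.55, ABPI assessment 63.74,
pathology 33.75, compression bandage 51.50, stocking 97.75, hospital
episode 18,331.60.

Four unit costs enter the care schedules but are not published anywhere and
ship as explicit, overridable assumptions (a notice is logged when a config
omits them): dressing consumables 15 AUD per change, a systemic-antibiotic
course 25 AUD per fortnight of infection, debridement 40 AUD per session,
and an outpatient-clinic visit priced at the NP consult rate. A
community-nurse visit is costed as one hour at the midpoint of the
published 24.74–37.05 hourly wage range (30.90 AUD). These assumptions move
absolute usual-care totals materially (usual care consumes dressings and
visits at twice the optimal-care frequency) and are the main reason
absolute cost totals should be read as indicative.

## Costing rules

Recurring state costs are frequency × unit cost per fortnight. Usual
unhealed care: 4 provider-mix-priced clinic visits, 4 dressing changes,
compression bandages for 50% of patients, and for the infected share two
weekly pathology tests plus antibiotics. Optimal unhealed care: 2 visits
(NP under Option 1; provider-mix under Option 2), 2 dressing changes,
bandages for everyone, and for the infected share two weekly debridements
plus antibiotics. One bandage kit is replaced per dressing change
(configurable, `bandages_per_dressing_change`): bandages are reapplied when
the wound is dressed. Healed-state prevention under optimal care amortises
a 3-monthly review (NP or GP by option) and a compression stocking over 6.5
cycles; usual care provides no post-healing care. One-off entry costs
attach to every new unhealed episode — incident, recurrent and, by default,
*not* hospital discharges (configurable) — including the prevalent cohort
at cycle 0, which starts treatment when the model starts: GP assessment
(usual); ABPI + NP + vascular surgeon (Option 1); ABPI + GP (Option 2);
plus a one-off pathology test for the infected share under optimal care. A
hospital admission incurs the episode payment on arrival.

Payer decomposition: hospital episodes split 40% Australian government /
60% State; compression products are fully federally funded under optimal
care, and under usual care split between out-of-pocket spending and
indirect government funding by a config fraction (default 0.556, the ratio
implied by the published national compression totals); all other categories
follow the jurisdiction profile's shares. Usual-care clinic visits are
provider-mix-priced because usual care is delivered by GPs, community
nurses and outpatient clinics in jurisdiction-specific proportions.

Accrual values start-of-cycle occupancy over the 130 lived cycles with no
half-cycle correction (a config flag enables the corrected average), which
matches a plain spreadsheet cohort sum; one-off costs are valued when their
flow arrives, including arrivals at the final time point (the event occurs
within the horizon). Discounting is `(1 + r)^(−t/26)` at r = 5%/year.
Costs and QALYs are tallied only for the affected sub-cohort — unhealed,
healed-with-history and hospitalised occupancy. The susceptible pool needs
no utility value: total QALY magnitudes (hundreds of thousands over ~300k
affected persons) are only consistent with affected-only accounting, and a
population-wide tally would swamp the comparison with identical
susceptible-pool terms. QALYs for a hospitalised cycle use the hospitalised
utility (0.54), not the unhealed value.

## Synthetic jurisdiction profiles

Per-State populations 60+, growth, mortality and payer shares are not
publicly deposited. The generator draws populations around the States'
approximate relative sizes and rescales them to sum exactly to 4,840,400 —
the national 60+ total uniquely consistent with a 1% prevalence yielding
48,404 affected persons at cycle 0. Growth uses an annual rate per
jurisdiction drawn from 2.5–3.5% (the observed expansion of the 60+ age
group in the 2010s), converted to a constant per-cycle inflow; mortality is
jittered in 2.54–3.10% around the national 2.82%. Payer-share archetypes
encode known funding differences: ACT-like profiles have zero out-of-pocket
dressings (consumables fully subsidised), QLD/VIC-like profiles 60–80%
out-of-pocket, others 35–55%. An AGGREGATE profile carries the national
population, summed growth and population-weighted shares; because the
cohort model is linear in the population, a harmonised aggregate run equals
the sum of per-State runs up to initial-count rounding (tested).

What the synthetic profiles do *not* emulate: the real supplementary
State-level unit-cost shares, true growth trajectories, and State-specific
clinical rates. Passing tests on this bundle therefore demonstrate the
qualitative conclusions — optimal care dominates in every jurisdiction
under both delivery options, savings grow with hospitalisation rate and
prevalence — and the share-independent national counts (ever-affected
~3×10⁵ persons; hospitalisations avoided ~2.1×10⁴), not exact State-level
cost totals.

## Sensitivity analyses

**One-way DSA.** Each input is varied to low/high endpoints holding the
rest at baseline and the pipeline re-run; entries are ranked by the swing
in NMB at λ = 64,000. Endpoints default to ±20% of baseline (truncated to
the domain) because the original low/high values are unpublished; the
usual-care hospitalisation rate instead spans its scenario range
(1.16–12.36% per year). Under these assumed ranges the utility weights
dominate the NMB tornado through the λ·ΔE term; the
hospitalisation-rate bar remains the widest *cost* driver relative to the
optimal-arm parameters and to recurrence, and unfavourable healing or
recurrence values never overturn cost savings. With CI-based utility ranges
the ordering could differ; the ranges are fully config-driven.

**Scenarios.** Usual-care annual hospitalisation rate ∈ {1.16%, 5.34%,
12.36%} (the optimal-care rate; the baseline restatement of 0.24/5 years;
the admissions-data estimate) replaces the 5-year input on the annual
horizon. Prevalence ∈ {0.33%, 0.5%, 1%, 1.69%} re-initialises cycle 0.

**PSA.** Probabilities, infection shares and utilities draw from beta
distributions, unit costs from gammas, each moment-matched to mean =
baseline and sd = cv × mean, independent across parameters; incidence and
mortality are drawn once and shared across arms, and the mortality draw
shifts each jurisdiction's own baseline multiplicatively. An infeasible
beta moment pair (sd ≥ √(m(1−m))) is shrunk to 95% of the support bound
and logged once. The published description fixes the families but not the
spreads; **cv = 0.2 is this package's single most consequential
assumption** for PSA outputs such as the probability of cost-effectiveness,
and is overridable in settings. cv = 0 reproduces the deterministic result
exactly (tested). The acceptability curve uses λ from 0 to 150,000 in
5,000 steps, always including 64,000. Default iterations: 10,000; the test
suite and acceptance script use 1,000, which bounds the Monte-Carlo error
of a ~0.9 probability near 1 percentage point while keeping runtimes in
seconds.

## Validation against an independent oracle

`microsim_oracle` simulates individuals one transition at a time with the
same per-cycle matrices, scaling the growth inflow to the simulated sample
with a fractional-remainder carry. The cohort trace is the expectation of
this process; the suite checks agreement of all occupancy proportions
within three binomial standard errors at 50,000 individuals over the full
horizon, plus exact behaviour in degenerate cases (certain healing, single
individuals).

## Numerical choices and degenerate inputs

Row sums are validated to 1e-12, person conservation to 1e-6 persons over
131 time points. Probabilities at 0 and 1 pass through conversion exactly.
PSA degenerate draws (cv = 0, or mean at a support endpoint) return the
baseline value. Zero-population or zero-prevalence runs are legal and
produce zero costs/QALYs. ICERs are suppressed in dominance quadrants
(class labels instead), and ΔE = 0 with ΔC > 0 reports an infinite ratio
rather than dividing by zero.

## Known limitations

Transition probabilities are time-constant (no ageing within the 60+
cohort, constant recurrence risk); growth inflow and mortality are
jurisdiction-constant per cycle. Private hospital admissions, productivity
losses and clinician-training costs are out of scope. Absolute cost totals
inherit the four assumed unit costs and the synthetic payer shares;
incremental *directions*, counts and probability statements are the robust
outputs. The PSA ignores parameter correlation (e.g. healing and recurrence
both improving with compression adherence), which likely understates the
spread of ΔE.
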