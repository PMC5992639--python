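# vlucea

Cost-effectiveness modelling of guideline-based care for venous leg ulcers
(VLUs) in Australia.

Chronic venous leg ulcers mainly affect people aged 60 and over; they are
slow to heal, frequently recur, and occasionally require hospital admission
for complications such as cellulitis. Clinical guidelines recommend
compression therapy as first-line treatment and prevention, but the
Australian health system does not reimburse compression products, and much
usual care falls short of the guideline. `vlucea` is a decision-analytic
package for health economists asking: what would it cost — and save — to
fund guideline-based ("optimal") VLU care nationally, compared with
continuing usual care?

## The model

A Markov cohort model follows the population aged 60+ through five mutually
exclusive health states — No VLU, Unhealed VLU, Healed, Complicated VLU with
hospitalisation, and Death — on fortnightly cycles for 130 cycles (5 years).
Transition probabilities arrive on their native horizons (3-month healing,
annual recurrence, 5-year or annual hospitalisation) and are converted to
per-cycle probabilities by the constant-hazard rule

    tp = 1 − (1 − tp_t)^(1/t)

where *t* is the native horizon in cycles. New 60-year-olds join the
susceptible pool each cycle; hospital stays last exactly one cycle. Costs
(AUD, 2015 prices) are assembled per state as frequency × unit cost from
each strategy's care schedule, decomposed by payer (Australian government,
State/Territory government, out-of-pocket) and category (compression
products, other dressings, services, hospital, medicines), with public
hospital episodes split 40% federal / 60% State. QALYs accrue as
utility × time in state; both streams are discounted at 5% per year and
tallied only for people with a VLU history. Strategies are compared by
incremental cost ΔC, incremental effect ΔE, the ICER (suppressed in
dominance quadrants), and net monetary benefit NMB = ΔE·λ − ΔC at a
willingness-to-pay λ = 64,000 AUD/QALY.

Uncertainty is handled three ways: one-way deterministic sensitivity
analysis (tornado), scenario analyses over the usual-care hospitalisation
rate and the baseline prevalence, and probabilistic sensitivity analysis
(beta distributions for probabilities and utilities, gamma for costs)
summarised as a cost-effectiveness plane and acceptability curve.

State-level inputs (60+ populations, growth, payer cost-shares) are not
publicly deposited; `vlucea.synthetic` generates labelled-synthetic
jurisdiction profiles whose populations sum exactly to the national 60+
total of 4,840,400. A vectorised individual-level microsimulation with the
same per-cycle probabilities serves as an independent oracle for the cohort
engine.

## Worked example

```sh
$ vlucea synth --seed 0 --out bundle.yaml
wrote synthetic bundle (9 profiles) to bundle.yaml

$ vlucea run bundle.yaml --jurisdiction AGGREGATE --outdir results
AGGREGATE option 1: dC = -2,832,476,861 AUD, dE = 27,390.447 QALY, dominant, NMB = 4,585,465,460 AUD

$ vlucea sensitivity bundle.yaml --mode psa --n 1000 --seed 1 --outdir results
PSA: P(cost-effective at 64,000/QALY) = 0.915; P(cost-saving) = 0.736
```

Reading the output: over 5 years, nationally, optimal care costs about
AUD 2.8 billion *less* than usual care while adding about 27,390
quality-adjusted life years — optimal care dominates (cheaper and more
effective), so no ICER is reported and the net monetary benefit at
64,000 AUD/QALY is about AUD 4.6 billion. Under parameter uncertainty,
91.5% of 1,000 Monte-Carlo draws have positive net benefit and 73.6% are
outright cost-saving. The `results/` directory holds the cohort traces,
payer-by-category cost tables, the CE-plane and CEAC points, and a
manifest recording the config checksum and seed.

The same analyses are available as library calls:

```python
from vlucea import generate_baseline_bundle, run_national

bundle = generate_baseline_bundle(seed=0)
res = run_national(bundle, option=1)
print(res.delta.icer_class, round(res.usual.hospitalisations - res.optimal.hospitalisations))
# dominant 21378
```

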