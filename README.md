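# cariesim

Tooth-level Markov Monte-Carlo microsimulation of proximal caries detection
on bitewing radiographs, **with versus without AI assistance**, and the full
health-economic comparison of the two strategies.

Dentists detect proximal (between-teeth) caries lesions on bitewing
radiographs with limited sensitivity, especially for early lesions.
Convolutional-network assistants read the same images with roughly twice the
sensitivity at slightly lower specificity.  Detection alone has no value —
health and cost consequences arise from the treatment decisions that follow:
early noncavitated lesions (E2/D1) can be arrested microinvasively by resin
infiltration, while missed lesions progress to cavitated dentin lesions
(D2/D3) that need a restoration and can start an escalating cascade of
re-restorations, crowns, root-canal treatments and ultimately extraction and
implant replacement.  This package simulates that whole pathway to answer:
*is AI-assisted caries detection cost-effective for a (German mixed-payer)
health-care system?*

## The model

One proximal surface per posterior permanent tooth of an initially
12-year-old individual is followed through 65 annual cycles.  Each cycle:

1. **Disease dynamics.** A sound surface develops a lesion arriving at stage
   E2, D1 or D2 with age-dependent exponential-decay hazards
   `m·a·2.7^(−b·α)`; an untreated lesion deepens one stage with power-law
   hazards `m·c·α^(−k)` (the initial stages carry a caries-risk multiplier,
   2.13 low / 2.63 high risk); infiltrated lesions progress with their own,
   flatter hazards.
2. **Detection and treatment.** A visual-tactile exam every cycle (blind to
   initial proximal lesions) and a bitewing radiograph every second cycle,
   read either by dentists alone (sensitivity 0.24/0.36/0.64 for E2/D1/D2+)
   or with AI assistance (0.68/0.68/0.58, specificity 0.86 vs 0.97/0.94/0.98).
   Detected initial lesions are infiltrated (base case) or restored (policy
   sensitivity analysis); detected advanced lesions get a two-surface
   composite, with a 0.3 pulp-exposure risk for deep (D3) lesions (95%
   direct capping / 5% immediate root-canal treatment).  False positives on
   sound surfaces are treated as initial lesions — money spent, no health
   gain.
3. **Failure cascade.** Existing work fails with annual probabilities from
   large cohort studies (composite 0.016, direct capping 0.111, vital crown
   0.036, nonvital crown 0.029 plus 0.021 endodontic, retreatments
   0.085/0.061, implant 0.010) and a categorical allocation to the follow-up
   procedure; crowns and implants are replaced at most once; extracted teeth
   are replaced by an implant-supported crown with probability 0.8.

**Effectiveness** is undiscounted tooth retention (years before extraction).
**Costs** are euro (2020) per tooth, discounted at 3%/a; visit-level fees
(bitewing pair, AI analysis at 8 €, assessment) are shared across 16 teeth.
Probabilistic sensitivity analysis draws every distributed parameter per
tooth from uniform/triangular distributions.  Strategies are compared by the
incremental cost-effectiveness ratio ICER = ΔC/ΔE on cohort means, the
cost-effectiveness-plane quadrant fractions and net-monetary-benefit
acceptability curves (λ·E − C) over bootstrap replicates of the paired
cohort means, and a ten-row univariate sensitivity table.

The repository ships the full epidemiological parameter table as JSON and a
**synthetic** placeholder fee schedule (`synthetic: true`) with realistic
clinical fee ordering; absolute euro outputs become authoritative only after
entering official BEMA/GOZ-derived fees into
`costs_appendix_template.json`.  Retention endpoints need no fee data.

## Worked example

```python
from cariesim import run_cohort, scenario, compare

ai   = run_cohort(scenario("base_case", strategy="ai"),      n=1000, seed=1)
ctrl = run_cohort(scenario("base_case", strategy="control"), n=1000, seed=1)
result = compare(ai, ctrl)
print(f"AI:      {ai.effectiveness.mean():.1f} retention years, {ai.cost_discounted.mean():.0f} EUR")
print(f"control: {ctrl.effectiveness.mean():.1f} retention years, {ctrl.cost_discounted.mean():.0f} EUR")
print(f"ICER: {result.icer:.1f} EUR per retention-year")
print(f"P(AI less costly and more effective): {result.quadrants['less_costly_more_effective']:.2f}")
```

prints

```
AI:      62.3 retention years, 250 EUR
control: 61.5 retention years, 263 EUR
ICER: -15.6 EUR per retention-year
P(AI less costly and more effective): 0.91
```

AI-assisted reading retains teeth ~0.8 years longer per tooth and — despite
the per-use AI fee and more false-positive infiltrations — saves money over
the life course by arresting early lesions before they enter the expensive
restorative cascade.  The negative ICER with positive ΔE means dominance:
better health at lower cost, in 91% of bootstrap replicates.  (Cost figures
use the synthetic fee schedule; see above.)  Under the all-restorative
policy variant the ranking reverses: the sensitive, less specific AI reader
then drags sound and early-lesion teeth into the restorative spiral.

The same analyses run from the shell:

```sh
cariesim simulate --scenario base_case --strategy ai --n 1000 --seed 1 --out runs/ai
cariesim compare --scenario base_case --n 1000 --seed 1 --out runs/cea
cariesim table2 --n 1000 --seed 1 --out runs/sensitivity.csv
cariesim fixtures-emit --what all --out fixtures/
```

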