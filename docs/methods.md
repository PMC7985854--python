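# Methods

## Model structure

`cariesim` is an individual-level (first-order Monte-Carlo) Markov
state-transition model.  The simulated unit is one proximal surface of a
posterior permanent tooth in an initially 12-year-old individual with a
vital pulp; at most one carious lesion is modelled per tooth, and teeth are
simulated independently (no mouth-level correlation).  Time advances in
annual cycles over a fixed horizon of 65 cycles (ages 12–77), chosen as a
mean-lifetime horizon consistent with the model's reported full-horizon
upper percentiles; it is configurable per scenario.

Health states: `SOUND`, `LESION(stage E2/D1/D2/D3, infiltrated flag)`,
`RESTORED(generation)`, `CAPPED`, `CROWN_VITAL`, `CROWN_NONVITAL`,
`NONSURG_RETREATED`, `SURG_RETREATED`, and after extraction `IMPLANT` or
`GONE`.  Retention years — the effectiveness measure — count the cycles
before extraction; implants never count.  E1 is not a separate state: the
accuracy and hazard tables provide no E1 column, so "initial" means
{E2, D1} and text-level E1/E2 labels map onto the single E2 state.

Within a cycle the order is: (1) disease dynamics, (2) scheduled exams and
the treatment they trigger, (3) failure draws for pre-existing work.  A
lesion arising in a cycle can therefore be found at that cycle's exam, and
work placed in a cycle cannot fail in the same cycle.

## Disease dynamics

Lesion *development* (incidence on a sound surface, arriving directly at
E2, D1 or D2; competing risks evaluated in that order, at most one event
per cycle):

| target | hazard | multiplier m |
|---|---|---|
| E2 | m · 0.57252 · 2.7^(−0.1472·α) | uniform 1.24–1.29 (point 1.26) |
| D1 | m · 0.0426 · 2.7^(−0.0521·α) | same |
| D2 | m · 0.57·0.0426 · 2.7^(−0.0521·α) | same |

Lesion *progression* (one stage per cycle):

| transition | hazard | multiplier |
|---|---|---|
| E2→D1 untreated | r · m · 3.0984 · α^(−1.343) | r = 2.13 (low) / 2.63 (high risk); m uniform 0.87–1.13 |
| D1→D2 untreated | r · m · 161.52 · α^(−2.078) | same |
| D2→D3 untreated | 1.32 · m · 161.52 · α^(−2.078) | fixed 1.32 replaces r |
| E2→D1 infiltrated | m · 0.4289 · α^(−1.391) | triangular 0.23–1–5.15 |
| D1→D2 infiltrated | m · 68.869 · α^(−2.078) | triangular 0.23–1–4.17 |

α is the attained age in years; all hazard values are clamped to [0, 1]
before use as per-cycle probabilities.  An infiltrated E2 that progresses
keeps its flag (and the infiltrated D1 hazard); the flag is dropped on
reaching D2, where infiltration is undefined.  Lesions are infiltrated at
most once; a D3 lesion is inert until detected.

### The age-argument reading

The hazard coefficients were originally tabulated with a doubled age
argument (`2.7^(−b·2α)`, `(2α)^(−k)`).  Both readings were implemented and
the choice is a single config switch (`age_factor`, default 1.0).  The
default evaluates at the attained age itself, for a substantive reason:
under the doubled-age form, untreated initial-lesion progression becomes so
slow (E2→D1 ≈ 0.09/yr at age 12, decaying fast) that even the control arm's
low-sensitivity biennial examination detects essentially every lesion
before it has consequences — the two detection strategies then differ by
< 0.1 retention years and the AI arm is *more* costly, i.e. the model loses
the phenomenon it exists to quantify.  With `age_factor = 1` the same
coefficients concentrate lesion activity in adolescence and penalise missed
early lesions, reproducing the expected strategy separation (base case
≈ 62.3 vs 61.5 retention years, AI dominant).  Users wanting the literal
doubled-age form set `age_factor: 2.0` in the parameter file.

## Detection and treatment

Visual-tactile examination runs every cycle (an annual-cycle rendering of
twice-yearly recall; the interval is configurable), bitewing radiography
every second cycle starting at cycle 0.  Per-stage accuracies (mode, with
triangular sampling ranges where interval estimates exist):

* visual-tactile: sensitivity 0 / 0 / 0.311 (0.270–0.353) for E2/D1/D2+,
  specificity 1 / 1 / 0.922;
* dentists' radiographs (control): sensitivity 0.24 (0.21–0.26),
  0.36 (0.24–0.49), 0.64 (0.59–0.70); specificity 0.97 (0.95–0.98),
  0.94 (0.89–0.97), 0.98 (0.97–0.98);
* AI-assisted radiographs: sensitivity 0.68 / 0.68 / 0.58, specificity
  0.86 / 0.86 / 0.96 (point values);
* an alternative control profile uses the pooled accuracy of the seven
  dentists who read the network's own test images — 0.36 (0.19–0.65)
  sensitivity and 0.91 (0.69–0.98) specificity applied across the initial
  stages, with the meta-analytic advanced-stage values retained, since no
  per-stage breakdown exists for these readers.

Due methods err independently given the truth; a lesion is detected (at its
true stage — no depth misgrading) if any method fires.  D3 lesions use the
advanced (D2) accuracy column.  A sound surface false-fires per method with
1 − specificity at the initial-lesion grade (the E2 column is used as the
method's sound-surface specificity; for the AI profile the two initial
columns are identical anyway).  False positives are always graded initial.

Treatment policy: detected initial lesions (including false positives) get
the policy's initial-lesion action — infiltration in the base case,
restoration in the all-restorative sensitivity analysis; advanced lesions
are always restored.  A surface infiltrated after a false positive is
book-kept and not re-billed on later false positives (configurable,
`refp_repeat`), which prevents unbounded false-positive cost accumulation.
Adherence is full: every true detection is treated.

Restoring a D3 lesion exposes the pulp with probability 0.3 (re-restoration:
0.10); exposed pulps receive direct capping with probability 0.95, otherwise
immediate root-canal treatment.  D2 (and initial-lesion) restorations carry
no pulpal risk.

## Failure cascade

Annual failure probabilities and allocations (all point estimates):
composite 0.016 → re-restore 0.45 / crown 0.10 / repair 0.10 / RCT 0.25 /
extract 0.10; direct capping 0.111 → RCT 0.95 / extract 0.05; vital crown
0.036 → RCT 0.25 / recement 0.15 / repair 0.10 / recrown 0.40 / extract
0.10; RCT 0.021 → nonsurgical retreat 0.20 / surgical retreat 0.30 /
extract 0.50; nonvital crown 0.029 → recement 0.20 / repair 0.10 / recrown
0.60 / extract 0.10; nonsurgical retreat 0.085 → surgical 0.25 / extract
0.75; surgical retreat 0.061 → extract 1.0; implant 0.010 → refix 0.60 /
recrown 0.20 / reimplant 0.20.

Structural rules: a restoration that was repaired or re-restored once is
crowned on its next failure; after RCT the tooth is crowned (nonvital) —
when the RCT is reached through an existing crown, that crown is retained;
nonvital crowned teeth draw the mechanical (0.029) and endodontic (0.021)
hazards independently each cycle, mechanical first; crowns are replaced at
most once, a second replacement need means extraction; extracted teeth are
replaced with an implant-supported crown with probability 0.8 (scenario
lever 0/1), implants are replaced at most once and a second implant failure
ends all care.  Repair, recementation and refixing are cost-only events.

## Costs and discounting

Every clinical event is priced from a JSON fee schedule (euro, 2020).
Visit-level fees — the bitewing pair, its AI analysis (8 € base case, 4/12 €
variants), and the assessment/advice of the visual-tactile exam — are
divided by a shared-cost divisor (default 16, the posterior teeth covered by
one bitewing pair).  A cost in cycle *t* is discounted by (1+r)^−t with
r = 3 %/a (1 %/5 % variants); no half-cycle correction.  Teeth that leave
the mouth stop accruing exam costs; implants accrue only their own
maintenance events.

Effectiveness is reported undiscounted.  The model's reported retention
means (≈ 62–64 of 65 possible years) are arithmetically incompatible with
discounted year-counts (a 3% annuity over 65 years sums to ≈ 29), and the
univariate discount-rate variants leave effectiveness unchanged — both
indicate that discounting applies to the cost stream.  A discounted
retention column is still computed and stored.

The shipped placeholder fee schedule is *synthetic*: fees are drawn
reproducibly from realistic euro ranges with the clinical ordering
infiltration < restoration < crown < implant-supported crown enforced by
disjoint ranges.  It makes the pipeline runnable and preserves directional
results; absolute euro endpoints (and the signs of near-zero ICER rows such
as the 0%-replacement variant) require the official BEMA/GOZ-derived fees,
entered via `costs_appendix_template.json`.

## Uncertainty analysis

PSA draws one realization of every distributed parameter per simulated
tooth (first-order and parameter uncertainty mixed, matching percentile
reporting across a 1,000-tooth cohort).  Symmetric printed ranges are
uniform; point estimates with interval estimates are triangular with the
mode at the point estimate (including the strongly asymmetric
infiltration-efficacy ranges, where a triangular mode-at-1 draw keeps the
point estimate modal while acknowledging the wide upper tail).  Draws are
independent; sampled probabilities are clamped to [0, 1].

Reproducibility: tooth *i* derives two RNG streams from
`SeedSequence(seed, spawn_key=(i, 0|1))` — one for parameter draws, one for
the event path — so cohorts are order-independent, bit-identical under a
fixed seed, and the two strategies run with common random numbers when
given the same seed (the full parameter set, both arms' accuracy draws
included, is sampled in a fixed order for every tooth).

The strategy comparison reports ΔC, ΔE and the ICER on cohort means (the
ICER is undefined and flagged when ΔE = 0; ΔC = 0 counts as "less costly"
and ΔE = 0 as "less effective" in quadrant assignment).  The
cost-effectiveness-plane cloud and the acceptability curves are computed by
default over 1,000 bootstrap replicates of the paired cohort means: the
decision-relevant sampling unit is the cohort, and per-tooth increments
concentrate at exactly ΔE = 0 because most individual teeth fare
identically under both strategies.  Per-tooth increments remain available
(`compare(..., level="tooth")`).

## Problem sizes and numerical choices

Default analyses use 1,000 teeth per strategy arm over 65 cycles, the
model's native cohort size; stochastic ordering tests in the suite use
4,000 teeth, and the dominance comparison 2,000, sizes at which the
retention effect (≈ 0.8 y, s.e. ≈ 0.1 y) is well resolved.  Per-tooth
discounted cost is heavy-tailed (implant events), so single-run ICERs at
n = 1,000 carry a standard error of roughly 8–9 € on ΔC; signs of
small-|ICER| scenario rows are accordingly unstable at that size.
Categorical allocation uses a single uniform draw against the cumulative
allocation map in its configured order, with the last category absorbing
float round-off.  Allocation maps must sum to 1 within 1e−9 or the
parameter file refuses to load.

## What the synthetic inputs do and do not show

The parameter table is generated in-package and ships as
`data/table1_base.json`; tests assert the shipped file matches the
generator.  The placeholder fee schedule emulates only the *structure* and
ordering of a real fee catalogue.  Passing tests therefore demonstrate the
epidemiological and decision-analytic machinery — retention endpoints,
dominance directions, policy reversal, scenario orderings — not the
absolute euro figures of any particular payer system.  Real teeth also
violate several simplifications: multiple surfaces and lesions per tooth,
correlated risk within a mouth, imperfect treatment adherence, lesion-depth
misgrading, secondary caries distinct from restoration failure, and
patient mortality within the horizon are all out of scope.
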