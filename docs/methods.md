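# Methods

This note documents the model, the parameter choices, the synthetic
cohorts and the numerical conventions behind `triplef`, including the
places where the design was genuinely open and what the package chose.

## Clinical model and assumptions

The package models one ED encounter of an adult (≥ 18 years) with
suspected systemic UTI in whom a urine culture, at least one blood-culture
set and a PCT value were obtained simultaneously.  All downstream labels
are pure functions of the raw encounter fields; nothing clinical is stored
pre-labelled, so any cohort — read from file, fixture-built or sampled —
flows through the identical rule path.

**Urine significance.**  A culture is *significant* at ≥ 10³ CFU/mL of an
accepted uropathogen in pure culture or in a mixture of at most two
pathogenic species; it is *sterile* with no growth and *contaminated*
otherwise (flora-only growth, > 2 pathogens, or no pathogen reaching the
threshold).  The organism vocabulary is configuration-loaded; the default
uropathogen list covers the common Enterobacterales,
*S. saprophyticus*, *S. aureus*, enterococci and *P. aeruginosa*.  Species
unknown to the vocabulary are treated as non-pathogenic with a warning
rather than rejected, since laboratory feeds routinely contain rare
organisms.

**Blood-culture adjudication.**  CoNS and viridans streptococci are
accepted as true bacteraemia only with ≥ 2 positive sets, or ≥ 1 set plus
an intravascular device; all other growth counts.  The source describes a
case-by-case review (positive-set count, devices, focus, risk factors)
without an explicit rule; this two-condition codification reflects
standard contaminant criteria and is configurable
(`AdjudicationRule(min_positive_sets, device_counts)`).

**Accordance** matches urine and blood organisms at species level after
string normalization; methicillin resistance does not affect matching.
The per-organism accordance table uses, as denominator, encounters with
that organism in the significant urine culture *and any* true bacteraemia
— one reading of an ambiguous definition, chosen because it makes the
discordant share interpretable per organism; it is isolated in
`organism_accordance_table` should users prefer another denominator.

**Classification.**  Six terminal rules run in fixed order (R1
*S. aureus* group, R2 bacteremic SUTI, R3 probable, R4 possible, R5
urocystitis, R6 ABU); the order resolves precedences the prose
definitions leave implicit, e.g. an accordant *S. aureus* bacteraemia is
the staphylococcal alternative-focus group, not bacteremic SUTI.  Two
operationalizations deserve explanation:

* *Systemic involvement* in the classifier is the clinical signal
  `F1 ∨ F2`.  PCT's primary role in the algorithm is as the trigger for
  obtaining cultures, not as a classifier input; folding `PCT ≥ 0.25`
  into the systemic criterion would also make the published marginal
  counts mutually unsatisfiable (it would force every
  ABU-without-alternative-focus encounter below the PCT cutoff, which
  the score-0/PCT joint count contradicts).  The PCT-inclusive variant
  remains available both as the standalone `has_systemic_features`
  (where laboratory findings do belong among systemic-reaction features)
  and via `classify_encounter(..., pct_in_systemic=True)`.
* *Alternative focus* inside rules R3/R4 means the **documented** focus.
  A focus established only by a discordant bacteraemia is recorded in
  `alternative_focus_present` and used by the stewardship split, but does
  not re-route classification; such encounters land in possible SUTI (no
  GU symptoms) or ABU (documented focus as well).  Using the broader
  definition inside R4 would cap possible-SUTI-with-focus at the handful
  of symptomatic cases and break the published stewardship arithmetic.

The cell "GU symptoms + no systemic involvement + alternative focus" is
unaddressed by the prose definitions; it classifies as urocystitis when
symptoms are lower-tract-only (urocystitis is defined purely by lower
symptoms plus absent systemic involvement) and otherwise as ABU, with a
note in the rule trace.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `pct_cutoff_ng_ml` | 0.25 | ng/mL (≡ µg/L) | established clinical PCT threshold for bacteraemia rule-out |
| `cfu_threshold` | 10³ | CFU/mL | significance threshold for quantitative urine culture |
| `fever_temp_threshold_c` | 38.0 | °C | optional numeric triage-temperature cut; F1 is otherwise documentation-based |
| `min_positive_sets` | 2 | sets | CoNS/viridans acceptance without a device |
| `ci_level` / `ci_method` | 0.95 / `"beta"` | — | exact Clopper–Pearson intervals; `"wilson"` available |

PCT is carried in ng/mL throughout; source material mixing ng/mL, pg/mL
and ng/L for the same 0.25 threshold is normalized to this one unit.

## The fixture cohort

`build_fixture_cohort` deterministically constructs one admissible
403-record cohort (138 sterile, 82 contaminated, 183 analyzable) whose
pipeline-derived aggregates hit every hard constraint in the ledger
(`default_constraints()`): the diagnosis partition 44/26/51/1/56/5, F
marginals 140/115/54, score-0 count 14, the PCT dichotomization cells
(53 below 0.25 ng/mL, 34 below 0.1, 6 below-cutoff score-0), bacteraemia
counts 65/49/16 with 6/2 below the cutoff, the alternative-focus
distribution (67 total: 30 pneumonia, 9 port, 9 SSTI, 4 influenza, 15
other), the focus splits (possible 20/31, ABU 42/14), 94 *E. coli*
bacteriurias, 32 two-pathogen mixtures and 91 women.  PCT values are a
small set of deterministic levels (0.05 / 0.15 / 1.0 / 2.0 ng/mL) placed
so that each dichotomized count holds exactly and the overall median is
1 ng/mL; joint cells that were never published are filled by a fixed
layout rather than fitted.  The seed permutes record order and ids only.

Where the printed tables contradict each other the ledger adopts one
resolution and flags the loser as a soft constraint: possible SUTI = 51
and ABU = 56 (the flow counts; the per-category table's 52/55 sum to 184),
ABU-with-focus = 42 and possible-with-focus = 20 (consistent with the
focus total 67 and the probable-threshold counts 45 + 62 = 107; the
41/55-patient variant yielding 30.1% is internally inconsistent with
those), and the *S. aureus* group size 5.  Two F3 cells deviate by one
from the per-category table *by necessity*: probable SUTI requires GU
symptoms, so its F3 count is 26 (printed 25), which with the fixed F3
marginal of 54 pushes the possible-SUTI cell to 6 (printed 7).  The
constraint checker (`check_constraints`) recounts everything through the
public pipeline with code independent of the builder.

## The stochastic sampler

`sample_cohort` draws i.i.d. encounters from a latent diagnosis-category
mixture: category probabilities are the fixture prevalences; F1/F2/F3 are
conditionally independent Bernoulli draws with the per-category rates of
the published cross table; urine organisms follow a frequency table with
*E. coli* at 51.4% and a 17.5% two-pathogen mixture rate; bacteremic
latents draw an accordant bloodstream organism with per-organism
probabilities (*E. coli* 0.853, *P. mirabilis* 0.60, *K. pneumoniae* and
*P. aeruginosa* 0.50, *E. faecalis* 0.167, *E. faecium* 0.0, default 0.5)
or a discordant *S. pneumoniae* otherwise; PCT is log-normal with median
2.0 ng/mL (bacteremic) or 0.37 ng/mL (others) and log-SD 1.5, calibrated
to the dichotomized fractions the analysis assumes (≈ 9% / 40% below
0.25 ng/mL).  Alternative-focus rates are 0.404 (possible), 0.745 (ABU)
and 1.0 (*S. aureus* group).

The sampler emulates marginal and first-order conditional structure only:
flags are independent given the category, there is no age/sex dependence,
no within-patient correlation between PCT and the F criteria beyond the
bacteraemia mixture, and contaminated/sterile cultures are not sampled.
Passing recovery tests therefore demonstrates that the pipeline inverts
the generator faithfully — not that the generator is a complete model of
real ED data.

## Numerical choices

* Exact binomial CIs via the beta-quantile method; tests verify them
  against an independent quantile oracle at 1e-9.
* Cohen's κ from the closed form `(Po − Pe)/(1 − Pe)` with the asymptotic
  SE `√(Po(1−Po)/n)/(1−Pe)`; degenerate margins (Pe = 1) report κ as
  undefined.  Computed from the fixture's PCT tables, κ = 0.250 (any
  bacteraemia) and 0.223 (accordant).
* Youden cutoff search scans every distinct observed value plus +∞ with
  the rule "positive iff marker ≥ threshold"; ties break to the smallest
  threshold.  On the fixture this scan is exercised but its selected
  cutoff reflects the fixture's coarse deterministic PCT levels, not a
  clinical recommendation — patient-level PCT distributions were never
  published, so cutoff *selection* is validated against brute force on
  random instances instead.
* Reported percentages round half-up to one decimal (`round_half_up`),
  matching clinical-table convention.
* Zero denominators flag the affected metric as undefined instead of
  raising; empty analyzable cohorts produce an explicit empty report.

## Problem sizes

The test suite runs the full 403-record fixture pipeline (a few seconds)
and parameter-recovery checks on sampled cohorts of n = 5000 with fixed
seeds and 3-binomial-SE tolerances, sizes at which the binomial noise is
small against the rates being recovered.  The acceptance script runs the
fixture pipeline once.

## Known limitations

* The classifier is faithful to a single-centre, retrospectively defined
  rule set; it performs no probability modelling and reports no
  uncertainty on the classification itself.
* Contaminant adjudication compresses a clinical review into two
  conditions; genuinely ambiguous CoNS cases will be mis-adjudicated in
  either direction depending on configuration.
* The accordance-table denominator convention is one of several
  defensible readings (see above).
* The fixture is *one* admissible cohort consistent with the published
  aggregates, not a reconstruction of the study's patients; conclusions
  about unpublished joint distributions cannot be drawn from it.
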