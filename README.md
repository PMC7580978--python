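# triplef

Rule-based classification of hospitalized emergency-department (ED)
patients with bacteriuria, built around the **3F ("triple F") score** and
supported by procalcitonin (PCT) and paired urine/blood cultures (PUB).

Distinguishing asymptomatic bacteriuria (ABU) from clinically relevant
urinary tract infection (UTI) is a recurring problem in acute medicine:
ABU is common in older adults and is routinely over-treated, while
urinary-source bacteraemia without genitourinary symptoms (USB) is easily
missed. `triplef` implements a transparent diagnostic algorithm for this
setting, the accuracy statistics used to evaluate it, and a synthetic
cohort generator for exercising the whole pipeline — aimed at clinical
epidemiologists and stewardship teams who want to study or adapt the
algorithm on their own data.

## The algorithm

Three binary criteria are scored per encounter:

| criterion | meaning |
|---|---|
| F1 "fever" | fever at triage or during the ED stay, measured fever, rigors or chills |
| F2 "failure" | failure/dysfunction of any organ system (brain, kidney, circulation, heart, liver, GI tract, metabolism, functional decline in the elderly) |
| F3 "focus" | focal genitourinary symptoms: dysuria, urgency, frequency, suprapubic tenderness (lower tract) or flank pain (upper tract) |

with the score `3F = F1 + F2 + F3 ∈ {0..3}`.  The workup rule obtains PUB
unless `3F = 0` and/or `PCT < 0.25 ng/mL`.  Urine cultures count as true
bacteriuria at ≥ 10³ CFU/mL of an accepted uropathogen, pure or mixed with
at most one other pathogen; CoNS/viridans blood isolates are adjudicated
as contaminants unless grown in ≥ 2 sets or with an intravascular device.
A bacteraemia is *accordant* when a bloodstream organism matches a
significant urine isolate.  Encounters are then partitioned into

* **bacteremic SUTI** — accordant true bacteraemia (USB when F3 = 0),
* **probable SUTI** — GU symptoms + systemic involvement, no alternative focus,
* **possible SUTI** — systemic involvement with either GU symptoms + focus
  or neither,
* **urocystitis** — lower-tract symptoms only, no systemic involvement,
* **ABU** — neither GU symptoms nor urinary-source systemic involvement,
* **_S. aureus_ group** — concomitant *S. aureus* bacteraemia and
  bacteriuria, handled as a disseminated staphylococcal infection.

On top of the classification the package computes diagnostic accuracy of
the PCT dichotomization (sensitivity/specificity/PPV/NPV with exact
binomial CIs, Youden's `J = Se + Sp − 1` and its optimal cutoff, Cohen's
κ) and the stewardship impact (blood cultures avoided; antimicrobials
withheld or narrowed at the possible/probable treatment thresholds).

## Worked example

```python
import triplef as tf

report = tf.run_pipeline(tf.RunConfig(source="fixture", seed=0))
print(report.cross_table.to_string(index=False))
```

```
       category  n  f1  f2  f3  alt_focus
bacteremic_suti 44  38  31  20          0
  probable_suti 26  24  17  26          0
  possible_suti 51  44  33   6         20
    urocystitis  1   0   0   1          0
            abu 56  32  29   0         42
   sa_alt_focus  5   2   5   1          5
```

The built-in fixture cohort holds 403 screened encounters; the
urine-culture filter excludes 138 sterile and 82 contaminated cultures,
and the rule pipeline classifies the remaining 183.  Of the 44 bacteremic
SUTI, 24 present without genitourinary symptoms — the USB group the
algorithm exists to catch.  The stewardship simulation on the same cohort
prints

```
blood cultures avoided: 61/183 (33.3%)
treatment threshold 'possible': withhold 14, narrow 42 -> 56/183 (30.6%) eligible
treatment threshold 'probable': withhold 45, narrow 62 -> 107/183 (58.5%) eligible
```

and the PCT accuracy report (any true bacteraemia) gives sensitivity
90.8%, specificity 39.8%, PPV 45.4% and NPV 88.7% — the high NPV is what
justifies skipping blood cultures below the cutoff.  The `examples/`
directory contains one short narrative script per capability
(classification, fixture pipeline, PCT accuracy, stewardship,
simulation + parameter recovery); a thin CLI mirrors them
(`triplef run|classify|evaluate-pct|stewardship|fixture|simulate|check`).

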