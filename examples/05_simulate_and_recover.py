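"""Sample a stochastic cohort and recover its generative parameters.

The sampler draws encounters from a latent diagnosis-category mixture
with the conditional F-criterion rates and per-organism urine/blood
accordance probabilities the analysis assumes; re-running the pipeline
on the raw fields recovers those rates.
"""

import numpy as np

import triplef as tf

sampled = tf.sample_cohort(n=5000, seed=42)
lat = sampled.latent

print("conditional F1 rates (generator -> empirical):")
for cat, (r1, _, _) in [("bacteremic", (0.864, 0.705, 0.455)),
                        ("probable", (0.923, 0.654, 0.962)),
                        ("abu", (0.582, 0.527, 0.0))]:
    sub = lat[lat.latent_category == cat]
    print(f"  {cat:11s} {r1:.3f} -> {sub.f1.mean():.3f}  (n={len(sub)})")

print("\nE. coli urine/blood accordance:")
num = den = 0
for enc in sampled.encounters:
    urine = tf.classify_urine_culture(enc.urine_culture)
    if (urine.status is not tf.UrineStatusValue.SIGNIFICANT
            or urine.organisms[0] != "Escherichia coli"):
        continue
    blood = tf.adjudicate_blood_cultures(enc.blood_culture_sets, enc)
    if blood.status is tf.BacteraemiaStatus.TRUE_BACTERAEMIA:
        den += 1
        num += "Escherichia coli" in blood.organisms
print(f"  generator 0.853 -> empirical {num / den:.3f}  (n={den})")

pct = np.array([e.pct_ng_ml for e in sampled.encounters])
bact = lat.bacteremic.to_numpy()
print(f"\nmedian PCT: bacteremic {np.median(pct[bact]):.2f} ng/mL, "
      f"non-bacteremic {np.median(pct[~bact]):.2f} ng/mL")

# Empirical rates sit within sampling error of the generator parameters;
# the PCT medians show the log-normal mixture separating the groups the
# way the 0.25 ng/mL dichotomization exploits.
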