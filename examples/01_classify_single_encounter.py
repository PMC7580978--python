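"""Score and classify one emergency-department encounter.

A 78-year-old woman with fever and acute kidney injury, no urinary
complaints, E. coli bacteriuria and a matching blood-culture isolate —
the classic urinary-source bacteraemia presentation the 3F workup is
designed to catch despite the absent genitourinary symptoms.
"""

import triplef as tf

encounter = tf.Encounter(
    encounter_id="DEMO-1",
    age_years=78,
    sex=tf.Sex.FEMALE,
    fever_at_triage=True,
    chills_or_rigors_reported=False,
    organ_dysfunctions={tf.OrganDysfunction.KIDNEY},
    gu_symptoms=set(),
    pct_ng_ml=1.8,
    urine_culture=tf.UrineCulture(
        tf.CollectionMethod.MIDSTREAM,
        [tf.Isolate("Escherichia coli", 1e5)],
    ),
    blood_culture_sets=[
        tf.BloodCultureSet("B1", [tf.Isolate("Escherichia coli")]),
        tf.BloodCultureSet("B2"),
    ],
)

triple_f = tf.compute_triple_f(encounter)
print(f"3F score: F1={triple_f.f1:d} F2={triple_f.f2:d} "
      f"F3={triple_f.f3:d} -> score {triple_f.score}")

workup = tf.recommend_workup(triple_f, encounter.pct_ng_ml)
print(f"workup recommendation at PCT {encounter.pct_ng_ml} ng/mL: "
      f"{workup.value}")

result = tf.classify_encounter(encounter)
print(f"bacteraemia: {result.bacteraemia.status.value} "
      f"({result.bacteraemia.accordance.value}, dominant uropathogen "
      f"{result.bacteraemia.dominant_uropathogen})")
print(f"diagnosis: {result.category.value}")
print(f"rule trace: {result.rationale}")

# Expected: score 2 (fever + failure, no focal symptoms), obtain_PUB,
# accordant bacteraemia -> bacteremic_suti. Without the paired cultures
# this patient would look like undifferentiated fever with incidental
# bacteriuria.
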