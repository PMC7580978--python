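"""Domain types for encounter-level data.

One :class:`Encounter` is a single emergency-department presentation of an
adult with suspected systemic urinary tract infection in whom a urine
culture, at least one blood-culture set and a procalcitonin (PCT) value
were obtained simultaneously.  The fields are the raw clinical inputs of
the 3F ("fever / failure / focus") algorithm; everything downstream
(urine-culture significance, bacteraemia adjudication, 3F score, diagnosis
category) is *derived* from these and never stored on the encounter.

PCT is carried in ng/mL (numerically identical to µg/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class CollectionMethod(str, Enum):
    MIDSTREAM = "midstream"
    SINGLE_CATHETER = "single_catheter"
    INDWELLING_AT_REPLACEMENT = "indwelling_at_replacement"


class OrganDysfunction(str, Enum):
    """Organ systems whose failure/dysfunction scores F2."""

    BRAIN = "brain"
    KIDNEY = "kidney"
    CIRCULATION = "circulation"
    HEART = "heart"
    LIVER = "liver"
    GI_TRACT = "gi_tract"
    METABOLISM = "metabolism"
    FUNCTIONAL_DECLINE_ELDERLY = "functional_decline_elderly"


class GUSymptom(str, Enum):
    """Focal genitourinary symptoms scoring F3.

    Flank pain is the upper-tract symptom; the other four are lower-tract
    symptoms (the distinction separates urocystitis from ABU).
    """

    DYSURIA = "dysuria"
    URGENCY = "urgency"
    FREQUENCY = "frequency"
    SUPRAPUBIC_TENDERNESS = "suprapubic_tenderness"
    FLANK_PAIN = "flank_pain"


LOWER_GU_SYMPTOMS = frozenset(
    {
        GUSymptom.DYSURIA,
        GUSymptom.URGENCY,
        GUSymptom.FREQUENCY,
        GUSymptom.SUPRAPUBIC_TENDERNESS,
    }
)


class AltFocus(str, Enum):
    """Documented alternative infectious-disease focus."""

    NONE = "none"
    PNEUMONIA = "pneumonia"
    PORT_INFECTION = "port_infection"
    SSTI = "ssti"
    INFLUENZA = "influenza"
    OTHER = "other"


class DiagnosisCategory(str, Enum):
    BACTEREMIC_SUTI = "bacteremic_suti"
    PROBABLE_SUTI = "probable_suti"
    POSSIBLE_SUTI = "possible_suti"
    UROCYSTITIS = "urocystitis"
    ABU = "abu"
    SA_ALT_FOCUS = "sa_alt_focus"
    EXCLUDED_STERILE = "excluded_sterile"
    EXCLUDED_CONTAMINATION = "excluded_contamination"


@dataclass
class Isolate:
    """A cultured organism; ``cfu_per_ml`` is set for urine isolates only."""

    species: str
    cfu_per_ml: float | None = None
    methicillin_resistant: bool | None = None


@dataclass
class UrineCulture:
    collection_method: CollectionMethod = CollectionMethod.MIDSTREAM
    isolates: list[Isolate] = field(default_factory=list)


@dataclass
class BloodCultureSet:
    set_id: str
    isolates: list[Isolate] = field(default_factory=list)

    @property
    def positive(self) -> bool:
        return bool(self.isolates)


@dataclass
class Encounter:
    encounter_id: str
    age_years: float
    sex: Sex
    fever_at_triage: bool
    chills_or_rigors_reported: bool
    organ_dysfunctions: set[OrganDysfunction]
    gu_symptoms: set[GUSymptom]
    pct_ng_ml: float
    urine_culture: UrineCulture
    blood_culture_sets: list[BloodCultureSet]
    intravascular_device: bool = False
    urinary_catheter: bool = False
    documented_alt_focus: AltFocus = AltFocus.NONE
    triage_temperature_c: float | None = None


def validate_encounter(enc: Encounter) -> list[str]:
    """Check type invariants; returns human-readable violations (no raising).

    An empty list means the encounter satisfies every invariant, including
    the adult-age inclusion criterion.
    """
    violations: list[str] = []
    if enc.age_years < 18:
        violations.append(
            f"{enc.encounter_id}: age_years={enc.age_years} violates the "
            "adult (>=18 years) inclusion criterion"
        )
    if enc.pct_ng_ml < 0:
        violations.append(
            f"{enc.encounter_id}: pct_ng_ml={enc.pct_ng_ml} must be non-negative"
        )
    for organ in enc.organ_dysfunctions:
        if not isinstance(organ, OrganDysfunction):
            violations.append(
                f"{enc.encounter_id}: unknown organ dysfunction {organ!r}"
            )
    for sym in enc.gu_symptoms:
        if not isinstance(sym, GUSymptom):
            violations.append(f"{enc.encounter_id}: unknown GU symptom {sym!r}")
    for iso in enc.urine_culture.isolates:
        if iso.cfu_per_ml is None:
            violations.append(
                f"{enc.encounter_id}: urine isolate {iso.species!r} lacks CFU/mL"
            )
        elif iso.cfu_per_ml < 0:
            violations.append(
                f"{enc.encounter_id}: urine isolate {iso.species!r} has "
                f"negative CFU/mL ({iso.cfu_per_ml})"
            )
    seen_ids: set[str] = set()
    for bc in enc.blood_culture_sets:
        if bc.set_id in seen_ids:
            violations.append(
                f"{enc.encounter_id}: duplicate blood-culture set id {bc.set_id!r}"
            )
        seen_ids.add(bc.set_id)
    return violations
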