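"""The 3F ("triple F") score and the five-way diagnosis classification.

The score sums three binary criteria:

* **F1 "fever"** — fever at triage or during the ED stay, an unequivocal
  statement of measured fever, or rigors/chills before presentation.
* **F2 "failure"** — failure or dysfunction of any organ system (brain,
  kidney, circulation, heart, liver, GI tract, metabolism, or failure of
  functioning in the elderly).
* **F3 "focus"** — focal genitourinary symptoms: acute dysuria, urgency,
  frequency, suprapubic tenderness (lower tract) or flank pain (upper
  tract).

Encounters with significant bacteriuria are then classified into exactly
one of: bacteremic SUTI (urine/blood-accordant true bacteraemia), probable
SUTI, possible SUTI, urocystitis, asymptomatic bacteriuria (ABU), or the
*S. aureus* alternative-focus group (concomitant *S. aureus* bacteraemia
and bacteriuria, treated as a disseminated staphylococcal infection rather
than a UTI).

Systemic involvement in the classification is the clinical signal F1 or F2;
procalcitonin (PCT) acts as the trigger for obtaining blood cultures
(:func:`recommend_workup`) and may optionally be folded into the systemic
criterion (``pct_in_systemic=True``), mirroring the listing of laboratory
findings among systemic-reaction features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .micro import (
    Accordance,
    AdjudicationRule,
    BacteraemiaAssessment,
    BacteraemiaStatus,
    CFU_THRESHOLD,
    DEFAULT_ADJUDICATION,
    UrineStatus,
    UrineStatusValue,
    adjudicate_blood_cultures,
    assess_accordance,
    classify_urine_culture,
)
from .model import AltFocus, DiagnosisCategory, Encounter, LOWER_GU_SYMPTOMS
from .vocab import DEFAULT_VOCABULARY, OrganismVocabulary, normalize_species

PCT_CUTOFF_NG_ML = 0.25  # established clinical PCT threshold, ng/mL (= ug/L)
FEVER_TEMP_THRESHOLD_C = 38.0

_S_AUREUS = "staphylococcus aureus"


@dataclass(frozen=True)
class TripleF:
    f1: bool
    f2: bool
    f3: bool

    @property
    def score(self) -> int:
        return int(self.f1) + int(self.f2) + int(self.f3)


class WorkupRecommendation(str, Enum):
    OBTAIN_PUB = "obtain_PUB"  # paired urine and blood cultures
    NO_BLOOD_CULTURES = "no_blood_cultures"


@dataclass
class ClassificationResult:
    category: DiagnosisCategory
    triple_f: TripleF
    systemic_features: bool
    alternative_focus_present: bool
    alternative_focus_label: str | None
    urine: UrineStatus
    bacteraemia: BacteraemiaAssessment
    rationale: list[str] = field(default_factory=list)


def score_f1(enc: Encounter,
             fever_temp_threshold_c: float = FEVER_TEMP_THRESHOLD_C) -> bool:
    """F1 "fever": documented fever indicators or measured triage fever."""
    if enc.fever_at_triage or enc.chills_or_rigors_reported:
        return True
    return (
        enc.triage_temperature_c is not None
        and enc.triage_temperature_c >= fever_temp_threshold_c
    )


def score_f2(enc: Encounter) -> bool:
    """F2 "failure": dysfunction of any organ system."""
    return bool(enc.organ_dysfunctions)


def score_f3(enc: Encounter) -> bool:
    """F3 "focus": any focal genitourinary symptom."""
    return bool(enc.gu_symptoms)


def lower_gu_only(enc: Encounter) -> bool:
    """True when GU symptoms are present and confined to the lower tract."""
    return bool(enc.gu_symptoms) and enc.gu_symptoms <= LOWER_GU_SYMPTOMS


def compute_triple_f(enc: Encounter) -> TripleF:
    return TripleF(score_f1(enc), score_f2(enc), score_f3(enc))


def has_systemic_features(
    enc: Encounter,
    triple_f: TripleF | None = None,
    pct_cutoff_ng_ml: float = PCT_CUTOFF_NG_ML,
    include_pct: bool = True,
) -> bool:
    """Features of a systemic reaction: fever, organ failure, or raised PCT."""
    tf = triple_f if triple_f is not None else compute_triple_f(enc)
    if tf.f1 or tf.f2:
        return True
    return include_pct and enc.pct_ng_ml >= pct_cutoff_ng_ml


def determine_alternative_focus(
    enc: Encounter, blood: BacteraemiaAssessment
) -> tuple[bool, str | None]:
    """Alternative infection focus: documented, or established by a
    discordant bacteraemia (the bloodstream organism points away from the
    urinary tract)."""
    if enc.documented_alt_focus is not AltFocus.NONE:
        return True, enc.documented_alt_focus.value
    if blood.accordance is Accordance.DISCORDANT:
        return True, "discordant bacteraemia"
    return False, None


def recommend_workup(
    triple_f: TripleF,
    pct_ng_ml: float,
    cutoff: float = PCT_CUTOFF_NG_ML,
) -> WorkupRecommendation:
    """Blood cultures are omitted at 3F score 0 and/or PCT below cutoff."""
    if triple_f.score == 0 or pct_ng_ml < cutoff:
        return WorkupRecommendation.NO_BLOOD_CULTURES
    return WorkupRecommendation.OBTAIN_PUB


def _has_s_aureus(organisms) -> bool:
    return any(normalize_species(o) == _S_AUREUS for o in organisms)


def classify_encounter(
    enc: Encounter,
    *,
    vocabulary: OrganismVocabulary = DEFAULT_VOCABULARY,
    cfu_threshold: float = CFU_THRESHOLD,
    adjudication_rule: AdjudicationRule = DEFAULT_ADJUDICATION,
    pct_cutoff_ng_ml: float = PCT_CUTOFF_NG_ML,
    pct_in_systemic: bool = False,
) -> ClassificationResult:
    """Classify an encounter with significant bacteriuria.

    Terminal rules are tried in fixed order; the first match decides:

    R1  *S. aureus* true bacteraemia with *S. aureus* bacteriuria
        -> SA_ALT_FOCUS (disseminated staphylococcal infection).
    R2  accordant true bacteraemia -> BACTEREMIC_SUTI.
    R3  F3 and systemic involvement, no documented alternative focus
        -> PROBABLE_SUTI.
    R4  F3 + systemic + documented focus, or no F3 + systemic + no
        documented focus -> POSSIBLE_SUTI.
    R5  lower-tract-only symptoms without systemic involvement
        -> UROCYSTITIS.
    R6  otherwise -> ABU (including systemic reactions fully attributed
        to an alternative focus).

    The documented focus gates R3/R4; a focus established only by a
    discordant bacteraemia is recorded in ``alternative_focus_present``
    (used by the stewardship analysis) but does not re-route the rules —
    such encounters fall into possible SUTI or ABU.  Raises ``ValueError``
    for sterile/contaminated urine cultures, which are excluded upstream.
    """
    urine = classify_urine_culture(enc.urine_culture, vocabulary, cfu_threshold)
    if urine.status is not UrineStatusValue.SIGNIFICANT:
        raise ValueError(
            f"classification requires significant bacteriuria, got "
            f"{urine.status.value} for {enc.encounter_id!r}"
        )
    blood = adjudicate_blood_cultures(
        enc.blood_culture_sets, enc, vocabulary, adjudication_rule
    )
    blood = assess_accordance(urine, blood)

    tf = compute_triple_f(enc)
    systemic = has_systemic_features(
        enc, tf, pct_cutoff_ng_ml, include_pct=pct_in_systemic
    )
    focus_present, focus_label = determine_alternative_focus(enc, blood)
    documented_focus = enc.documented_alt_focus is not AltFocus.NONE
    lower_only = lower_gu_only(enc)

    trace: list[str] = []
    bacteremic = blood.status is BacteraemiaStatus.TRUE_BACTERAEMIA
    if (
        bacteremic
        and _has_s_aureus(blood.organisms)
        and _has_s_aureus(urine.organisms)
    ):
        trace.append("R1:s_aureus_bacteraemia_with_bacteriuria")
        category = DiagnosisCategory.SA_ALT_FOCUS
    elif bacteremic and blood.accordance is Accordance.ACCORDANT:
        trace.append("R2:accordant_bacteraemia")
        category = DiagnosisCategory.BACTEREMIC_SUTI
    elif tf.f3 and systemic and not documented_focus:
        trace.append("R3:gu_symptoms_systemic_no_focus")
        category = DiagnosisCategory.PROBABLE_SUTI
    elif systemic and (tf.f3 == documented_focus):
        trace.append("R4:possible_suti")
        category = DiagnosisCategory.POSSIBLE_SUTI
    elif lower_only and not systemic:
        trace.append("R5:lower_gu_only_no_systemic")
        if documented_focus:
            trace.append("note:alternative_focus_present_without_systemic")
        category = DiagnosisCategory.UROCYSTITIS
    else:
        trace.append("R6:abu")
        if systemic and focus_present:
            trace.append("note:systemic_attributed_to_alternative_focus")
        category = DiagnosisCategory.ABU

    return ClassificationResult(
        category=category,
        triple_f=tf,
        systemic_features=systemic,
        alternative_focus_present=focus_present,
        alternative_focus_label=focus_label,
        urine=urine,
        bacteraemia=blood,
        rationale=trace,
    )
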