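"""Stewardship impact of the 3F algorithm.

Two quantities are simulated on a classified cohort:

* **Blood cultures avoided** — under the workup rule, no blood cultures
  are drawn at 3F score 0 and/or PCT < 0.25 ng/mL; the union of the two
  groups (without double counting) is the avoidable fraction.
* **Antimicrobial therapy withheld or narrowed** — with empiric treatment
  triggered at the *possible*-SUTI threshold, therapy is withheld in ABU
  without an alternative focus and narrowed (e.g. ampicillin/sulbactam for
  pneumonia or SSTI instead of broad urosepsis coverage) in ABU with one.
  At the *probable* threshold, possible-SUTI encounters are additionally
  withheld/narrowed by their alternative-focus status.  Urocystitis,
  probable and bacteremic SUTI and the *S. aureus* group always remain on
  treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .model import DiagnosisCategory, Encounter
from .scoring import (
    PCT_CUTOFF_NG_ML,
    ClassificationResult,
    WorkupRecommendation,
    compute_triple_f,
    recommend_workup,
)


class TreatmentThreshold(str, Enum):
    POSSIBLE = "possible"
    PROBABLE = "probable"


@dataclass(frozen=True)
class BCAvoidanceReport:
    n_total: int
    n_bc_avoided: int

    @property
    def bc_avoided_fraction(self) -> float:
        return self.n_bc_avoided / self.n_total if self.n_total else 0.0


@dataclass(frozen=True)
class ABSImpactReport:
    threshold: TreatmentThreshold
    n_total: int
    n_withheld: int
    n_narrowed: int

    @property
    def n_eligible(self) -> int:
        return self.n_withheld + self.n_narrowed

    @property
    def eligible_fraction(self) -> float:
        return self.n_eligible / self.n_total if self.n_total else 0.0


def simulate_bc_avoidance(
    cohort: Sequence[Encounter], pct_cutoff_ng_ml: float = PCT_CUTOFF_NG_ML
) -> BCAvoidanceReport:
    """Count encounters for which the workup rule omits blood cultures."""
    n_total = 0
    avoided = 0
    for enc in cohort:
        if enc.pct_ng_ml is None:
            warnings.warn(
                f"{enc.encounter_id!r}: missing PCT, excluded from the "
                "blood-culture avoidance simulation"
            )
            continue
        n_total += 1
        rec = recommend_workup(
            compute_triple_f(enc), enc.pct_ng_ml, pct_cutoff_ng_ml
        )
        if rec is WorkupRecommendation.NO_BLOOD_CULTURES:
            avoided += 1
    return BCAvoidanceReport(n_total, avoided)


def simulate_abs_impact(
    results: Sequence[ClassificationResult],
    threshold: TreatmentThreshold | str,
) -> ABSImpactReport:
    """Withheld/narrowed antimicrobial counts at a treatment threshold."""
    threshold = TreatmentThreshold(threshold)
    withheld = 0
    narrowed = 0
    eligible_categories = {DiagnosisCategory.ABU}
    if threshold is TreatmentThreshold.PROBABLE:
        eligible_categories.add(DiagnosisCategory.POSSIBLE_SUTI)
    for res in results:
        if res.category not in eligible_categories:
            continue
        if res.alternative_focus_present:
            narrowed += 1
        else:
            withheld += 1
    return ABSImpactReport(threshold, len(results), withheld, narrowed)
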