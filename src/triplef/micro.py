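"""Microbiological decision rules.

Three steps turn raw cultures into analysable microbiology:

1. **Urine significance** — quantitative cultures count as true bacteriuria
   at >= 10^3 CFU/mL of an accepted uropathogen, in pure culture or a mixed
   culture of at most two pathogens.  Flora-only growth, more than two
   pathogenic species, or pathogens below the CFU threshold are treated as
   contamination; no growth is sterile.
2. **Blood-culture adjudication** — any growth of a species outside the
   CoNS/viridans contaminant-review group is accepted as true bacteraemia.
   CoNS and viridans streptococci count as true bacteraemia only when grown
   in at least two separate sets, or in one set in a patient with an
   intravascular device; otherwise they are contaminants.
3. **Accordance** — a true bacteraemia is *accordant* when at least one
   bloodstream organism is also among the significant urine isolates
   (matching at species level), and *discordant* otherwise.  Accordance
   identifies the dominant uropathogen when the urine grew two species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .model import BloodCultureSet, Encounter, Isolate, UrineCulture
from .vocab import DEFAULT_VOCABULARY, OrganismVocabulary, normalize_species

logger = logging.getLogger(__name__)

CFU_THRESHOLD = 1_000  # CFU/mL significance threshold for uropathogens
MAX_MIXED_PATHOGENS = 2


class UrineStatusValue(str, Enum):
    SIGNIFICANT = "significant"
    STERILE = "sterile"
    CONTAMINATED = "contaminated"


@dataclass
class UrineStatus:
    status: UrineStatusValue
    significant_isolates: list[Isolate] = field(default_factory=list)

    @property
    def organisms(self) -> list[str]:
        return [i.species for i in self.significant_isolates]


class BacteraemiaStatus(str, Enum):
    NONE = "none"
    CONTAMINANT_ONLY = "contaminant_only"
    TRUE_BACTERAEMIA = "true_bacteraemia"


class Accordance(str, Enum):
    NOT_APPLICABLE = "not_applicable"
    ACCORDANT = "accordant"
    DISCORDANT = "discordant"


@dataclass
class BacteraemiaAssessment:
    status: BacteraemiaStatus
    organisms: list[str] = field(default_factory=list)
    accordance: Accordance = Accordance.NOT_APPLICABLE
    dominant_uropathogen: str | None = None


@dataclass(frozen=True)
class AdjudicationRule:
    """Contaminant-review rule for CoNS/viridans growth.

    True bacteraemia requires >= ``min_positive_sets`` positive sets, or
    >= 1 positive set together with an intravascular device when
    ``device_counts`` is set.
    """

    min_positive_sets: int = 2
    device_counts: bool = True


DEFAULT_ADJUDICATION = AdjudicationRule()


def classify_urine_culture(
    uc: UrineCulture,
    vocabulary: OrganismVocabulary = DEFAULT_VOCABULARY,
    cfu_threshold: float = CFU_THRESHOLD,
) -> UrineStatus:
    """Partition a urine culture into significant / sterile / contaminated."""
    if not uc.isolates:
        return UrineStatus(UrineStatusValue.STERILE)
    pathogenic: list[Isolate] = []
    for iso in uc.isolates:
        cls = vocabulary.classify_species(iso.species)
        if cls == "uropathogen":
            pathogenic.append(iso)
        elif cls == "other":
            logger.warning(
                "species %r not in vocabulary; treated as non-pathogenic "
                "flora for urine significance", iso.species,
            )
    if not pathogenic or len(pathogenic) > MAX_MIXED_PATHOGENS:
        return UrineStatus(UrineStatusValue.CONTAMINATED)
    qualifying = [
        i for i in pathogenic
        if i.cfu_per_ml is not None and i.cfu_per_ml >= cfu_threshold
    ]
    if not qualifying:
        return UrineStatus(UrineStatusValue.CONTAMINATED)
    return UrineStatus(UrineStatusValue.SIGNIFICANT, qualifying)


def adjudicate_blood_cultures(
    sets: Sequence[BloodCultureSet],
    enc: Encounter | None = None,
    vocabulary: OrganismVocabulary = DEFAULT_VOCABULARY,
    rule: AdjudicationRule = DEFAULT_ADJUDICATION,
) -> BacteraemiaAssessment:
    """Adjudicate blood-culture sets into none / contaminant-only / true.

    ``enc`` supplies the intravascular-device flag; accordance is left
    ``not_applicable`` until :func:`assess_accordance` is called.
    """
    if not sets:
        raise ValueError("at least one blood-culture set is required")
    device = bool(enc.intravascular_device) if enc is not None else False

    sets_by_species: dict[str, int] = {}
    display: dict[str, str] = {}
    for s in sets:
        seen: set[str] = set()
        for iso in s.isolates:
            key = normalize_species(iso.species)
            if key not in seen:
                sets_by_species[key] = sets_by_species.get(key, 0) + 1
                display.setdefault(key, iso.species)
                seen.add(key)

    if not sets_by_species:
        return BacteraemiaAssessment(BacteraemiaStatus.NONE)

    true_orgs: list[str] = []
    any_contaminant = False
    for key, n_pos in sets_by_species.items():
        cls = vocabulary.classify_species(display[key])
        if cls == "contaminant_review":
            accepted = n_pos >= rule.min_positive_sets or (
                rule.device_counts and device and n_pos >= 1
            )
            if accepted:
                true_orgs.append(display[key])
            else:
                any_contaminant = True
        else:
            true_orgs.append(display[key])
    if true_orgs:
        return BacteraemiaAssessment(
            BacteraemiaStatus.TRUE_BACTERAEMIA, organisms=true_orgs
        )
    assert any_contaminant
    return BacteraemiaAssessment(BacteraemiaStatus.CONTAMINANT_ONLY)


def assess_accordance(
    urine: UrineStatus, blood: BacteraemiaAssessment
) -> BacteraemiaAssessment:
    """Fill the accordance field of an adjudicated bacteraemia assessment."""
    if urine.status is not UrineStatusValue.SIGNIFICANT:
        raise ValueError(
            "accordance is defined only for significant urine cultures"
        )
    if blood.status is not BacteraemiaStatus.TRUE_BACTERAEMIA:
        blood.accordance = Accordance.NOT_APPLICABLE
        blood.dominant_uropathogen = None
        return blood
    urine_keys = {normalize_species(o): o for o in urine.organisms}
    shared = [o for o in blood.organisms if normalize_species(o) in urine_keys]
    if shared:
        blood.accordance = Accordance.ACCORDANT
        blood.dominant_uropathogen = urine_keys[normalize_species(shared[0])]
    else:
        blood.accordance = Accordance.DISCORDANT
        blood.dominant_uropathogen = None
    return blood


def organism_accordance_table(
    assessed: Iterable[tuple[UrineStatus, BacteraemiaAssessment]],
) -> dict[str, float]:
    """Per-organism accordance fractions.

    For each urine organism: numerator = encounters where that organism was
    accordant in blood; denominator = encounters with that organism in the
    significant urine culture and any true bacteraemia.  Organisms never
    seen with a true bacteraemia are omitted (zero denominator).
    """
    num: dict[str, int] = {}
    den: dict[str, int] = {}
    display: dict[str, str] = {}
    for urine, blood in assessed:
        if urine.status is not UrineStatusValue.SIGNIFICANT:
            continue
        if blood.status is not BacteraemiaStatus.TRUE_BACTERAEMIA:
            continue
        blood_keys = {normalize_species(o) for o in blood.organisms}
        for org in urine.organisms:
            key = normalize_species(org)
            display.setdefault(key, org)
            den[key] = den.get(key, 0) + 1
            if key in blood_keys:
                num[key] = num.get(key, 0) + 1
    table = {}
    for key, d in den.items():
        table[display[key]] = num.get(key, 0) / d
    return table
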