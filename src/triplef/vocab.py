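"""Controlled organism vocabulary.

Species isolated from urine or blood are interpreted against three lists:

* ``uropathogens`` — species accepted as causes of true bacteriuria
  (Enterobacterales, *S. saprophyticus*, *S. aureus*, enterococci,
  *P. aeruginosa*).  Genus-level entries are written ``"Klebsiella spp."``
  and match any species of that genus.
* ``flora`` — normal urogenital flora; growth of these alone marks a urine
  culture as contaminated.
* ``contaminant_review`` — coagulase-negative staphylococci and viridans
  group streptococci, which in blood cultures are adjudicated separately
  (number of positive sets, intravascular devices) rather than accepted
  outright.

A fourth list, ``blood_pathogens``, names recognized invasive pathogens
that are not accepted uropathogens (e.g. *S. pneumoniae*); in blood they
count as true bacteraemia, in urine as non-pathogenic.  Species on no list
fall into class ``"other"`` and are treated like flora with a warning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

UROPATHOGEN = "uropathogen"
FLORA = "flora"
CONTAMINANT_REVIEW = "contaminant_review"
BLOOD_PATHOGEN = "pathogen"
OTHER = "other"


def normalize_species(name: str) -> str:
    """Canonical form used for matching: lower-case, single-spaced."""
    return re.sub(r"\s+", " ", name.strip()).lower()


def _genus(name: str) -> str:
    return normalize_species(name).split(" ")[0]


DEFAULT_UROPATHOGENS = (
    "Escherichia coli",
    "Staphylococcus saprophyticus",
    "Staphylococcus aureus",
    "Klebsiella spp.",
    "Enterobacter spp.",
    "Proteus spp.",
    "Morganella morganii",
    "Enterococcus spp.",
    "Pseudomonas aeruginosa",
    "Citrobacter spp.",
    "Serratia marcescens",
)

DEFAULT_FLORA = (
    "Lactobacillus spp.",
    "Corynebacterium spp.",
    "Gardnerella vaginalis",
    "Bifidobacterium spp.",
    "mixed skin flora",
    "mixed urogenital flora",
)

DEFAULT_CONTAMINANT_REVIEW = (
    "coagulase-negative staphylococci",
    "Staphylococcus epidermidis",
    "Staphylococcus haemolyticus",
    "Staphylococcus hominis",
    "Staphylococcus capitis",
    "viridans group streptococci",
    "Streptococcus mitis",
    "Streptococcus oralis",
    "Streptococcus sanguinis",
    "Streptococcus salivarius",
)

DEFAULT_BLOOD_PATHOGENS = (
    "Streptococcus pneumoniae",
    "Streptococcus pyogenes",
    "Streptococcus agalactiae",
    "Streptococcus dysgalactiae",
    "Listeria monocytogenes",
    "Haemophilus influenzae",
)


@dataclass(frozen=True)
class OrganismVocabulary:
    uropathogens: tuple[str, ...] = DEFAULT_UROPATHOGENS
    flora: tuple[str, ...] = DEFAULT_FLORA
    contaminant_review: tuple[str, ...] = DEFAULT_CONTAMINANT_REVIEW
    blood_pathogens: tuple[str, ...] = DEFAULT_BLOOD_PATHOGENS

    def _match(self, entries: Iterable[str], species: str) -> bool:
        norm = normalize_species(species)
        genus = _genus(species)
        for entry in entries:
            e = normalize_species(entry)
            if e == norm:
                return True
            if e.endswith(" spp.") and e[: -len(" spp.")] == genus:
                return True
        return False

    def classify_species(self, species: str) -> str:
        """Return one of ``uropathogen | contaminant_review | flora | other``."""
        if self._match(self.uropathogens, species):
            return UROPATHOGEN
        if self._match(self.contaminant_review, species):
            return CONTAMINANT_REVIEW
        if self._match(self.flora, species):
            return FLORA
        if self._match(self.blood_pathogens, species):
            return BLOOD_PATHOGEN
        return OTHER

    def is_uropathogen(self, species: str) -> bool:
        return self.classify_species(species) == UROPATHOGEN

    def is_known(self, species: str) -> bool:
        return self.classify_species(species) != OTHER

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "OrganismVocabulary":
        block = cfg.get("organisms", cfg)
        return cls(
            uropathogens=tuple(block.get("uropathogens", DEFAULT_UROPATHOGENS)),
            flora=tuple(block.get("flora", DEFAULT_FLORA)),
            contaminant_review=tuple(
                block.get("contaminant_review", DEFAULT_CONTAMINANT_REVIEW)
            ),
            blood_pathogens=tuple(
                block.get("blood_pathogens", DEFAULT_BLOOD_PATHOGENS)
            ),
        )

    @classmethod
    def from_yaml(cls, path) -> "OrganismVocabulary":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


DEFAULT_VOCABULARY = OrganismVocabulary()
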