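"""Cohort readers and writers (CSV and JSON).

CSV schema: one row per encounter, list-valued fields semicolon-joined.

``urine_isolates`` tokens are ``species:cfu``; ``bc_sets`` tokens are
``set_id:species,species`` (empty species list = negative set).  A species
may carry a ``[MRSA]`` / ``[MSSA]`` suffix encoding the methicillin
resistance flag of *S. aureus*.  The JSON format holds the same fields with
lists as arrays; both round-trip losslessly.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

from .model import (
    AltFocus,
    BloodCultureSet,
    CollectionMethod,
    Encounter,
    GUSymptom,
    Isolate,
    OrganDysfunction,
    Sex,
    UrineCulture,
)
from .vocab import DEFAULT_VOCABULARY, OrganismVocabulary

CSV_COLUMNS = [
    "encounter_id",
    "age_years",
    "sex",
    "fever_at_triage",
    "chills_or_rigors_reported",
    "organ_dysfunctions",
    "gu_symptoms",
    "pct_ng_ml",
    "urine_collection_method",
    "urine_isolates",
    "bc_sets",
    "intravascular_device",
    "urinary_catheter",
    "documented_alt_focus",
]


class SchemaError(ValueError):
    """A mandatory column/field is missing or malformed."""


class VocabularyError(ValueError):
    """A species string is not in the configured organism vocabulary."""


def _species_token(iso: Isolate) -> str:
    tok = iso.species
    if iso.methicillin_resistant is True:
        tok += "[MRSA]"
    elif iso.methicillin_resistant is False:
        tok += "[MSSA]"
    return tok


def _parse_species_token(tok: str) -> tuple[str, bool | None]:
    mr: bool | None = None
    if tok.endswith("[MRSA]"):
        mr, tok = True, tok[: -len("[MRSA]")]
    elif tok.endswith("[MSSA]"):
        mr, tok = False, tok[: -len("[MSSA]")]
    return tok, mr


def _num(x: float) -> float | int:
    return int(x) if float(x).is_integer() else float(x)


def _urine_tokens(uc: UrineCulture) -> str:
    return ";".join(
        f"{_species_token(i)}:{_num(i.cfu_per_ml)}" for i in uc.isolates
    )


def _bc_tokens(sets: Sequence[BloodCultureSet]) -> str:
    return ";".join(
        f"{s.set_id}:{','.join(_species_token(i) for i in s.isolates)}"
        for s in sets
    )


def encounter_to_row(enc: Encounter) -> dict[str, str]:
    return {
        "encounter_id": enc.encounter_id,
        "age_years": str(_num(enc.age_years)),
        "sex": enc.sex.value,
        "fever_at_triage": str(int(enc.fever_at_triage)),
        "chills_or_rigors_reported": str(int(enc.chills_or_rigors_reported)),
        "organ_dysfunctions": ";".join(
            sorted(o.value for o in enc.organ_dysfunctions)
        ),
        "gu_symptoms": ";".join(sorted(s.value for s in enc.gu_symptoms)),
        "pct_ng_ml": str(_num(enc.pct_ng_ml)),
        "urine_collection_method": enc.urine_culture.collection_method.value,
        "urine_isolates": _urine_tokens(enc.urine_culture),
        "bc_sets": _bc_tokens(enc.blood_culture_sets),
        "intravascular_device": str(int(enc.intravascular_device)),
        "urinary_catheter": str(int(enc.urinary_catheter)),
        "documented_alt_focus": enc.documented_alt_focus.value,
    }


def _check_species(species: str, vocabulary: OrganismVocabulary,
                   row_id: str, strict: bool) -> None:
    if not vocabulary.is_known(species):
        msg = f"unknown species {species!r} in record {row_id!r}"
        if strict:
            raise VocabularyError(msg)
        warnings.warn(msg)


def row_to_encounter(row: dict[str, str], *,
                     vocabulary: OrganismVocabulary = DEFAULT_VOCABULARY,
                     strict_species: bool = False) -> Encounter:
    for col in CSV_COLUMNS:
        if col not in row or row[col] is None:
            raise SchemaError(f"missing mandatory column {col!r}")
    rid = row["encounter_id"]
    isolates = []
    if row["urine_isolates"]:
        for tok in row["urine_isolates"].split(";"):
            sp, cfu = tok.rsplit(":", 1)
            sp, mr = _parse_species_token(sp)
            _check_species(sp, vocabulary, rid, strict_species)
            isolates.append(Isolate(sp, float(cfu), mr))
    bc_sets = []
    if row["bc_sets"]:
        for tok in row["bc_sets"].split(";"):
            set_id, species_csv = tok.split(":", 1)
            isos = []
            if species_csv:
                for sp_tok in species_csv.split(","):
                    sp, mr = _parse_species_token(sp_tok)
                    _check_species(sp, vocabulary, rid, strict_species)
                    isos.append(Isolate(sp, None, mr))
            bc_sets.append(BloodCultureSet(set_id, isos))
    enc = Encounter(
        encounter_id=rid,
        age_years=float(row["age_years"]),
        sex=Sex(row["sex"]),
        fever_at_triage=bool(int(row["fever_at_triage"])),
        chills_or_rigors_reported=bool(int(row["chills_or_rigors_reported"])),
        organ_dysfunctions={
            OrganDysfunction(t)
            for t in row["organ_dysfunctions"].split(";")
            if t
        },
        gu_symptoms={GUSymptom(t) for t in row["gu_symptoms"].split(";") if t},
        pct_ng_ml=float(row["pct_ng_ml"]),
        urine_culture=UrineCulture(
            CollectionMethod(row["urine_collection_method"]), isolates
        ),
        blood_culture_sets=bc_sets,
        intravascular_device=bool(int(row["intravascular_device"])),
        urinary_catheter=bool(int(row["urinary_catheter"])),
        documented_alt_focus=AltFocus(row["documented_alt_focus"]),
    )
    if enc.age_years < 18:
        warnings.warn(
            f"record {rid!r}: age {enc.age_years} violates the >=18 "
            "inclusion criterion"
        )
    return enc


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "json" if str(path).endswith(".json") else "csv"


def read_cohort(path, format: str | None = None, *,
                vocabulary: OrganismVocabulary = DEFAULT_VOCABULARY,
                strict_species: bool = False) -> list[Encounter]:
    """Read a cohort file; row order is preserved.

    Unknown species raise :class:`VocabularyError` when
    ``strict_species=True`` and warn otherwise; under-age records are
    returned with a warning (downstream validation flags them).
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            for col in CSV_COLUMNS:
                if col not in header:
                    raise SchemaError(f"missing mandatory column {col!r}")
            rows = list(reader)
    elif fmt == "json":
        data = json.loads(path.read_text())
        rows = [{k: str(v) for k, v in rec.items()} for rec in data]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return [
        row_to_encounter(r, vocabulary=vocabulary,
                         strict_species=strict_species)
        for r in rows
    ]


def write_cohort(cohort: Iterable[Encounter], path,
                 format: str | None = None) -> None:
    """Serialize a cohort losslessly with stable column/field order."""
    fmt = _infer_format(path, format)
    path = Path(path)
    rows = [encounter_to_row(e) for e in cohort]
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
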