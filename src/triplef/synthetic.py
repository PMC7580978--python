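"""Synthetic cohorts: a constraint-built fixture and a stochastic sampler.

The study deposited no patient-level data, so two generators stand in:

* :func:`build_fixture_cohort` deterministically constructs one admissible
  403-encounter cohort (220 excluded by the urine-culture filter, 183
  analyzable) whose *raw fields only* are written; running the full
  pipeline (urine significance -> adjudication/accordance -> 3F scoring ->
  classification -> stewardship) reproduces every printed aggregate in the
  constraint ledger exactly.  The seed permutes row order and ids only —
  aggregates never depend on it.
* :func:`sample_cohort` draws i.i.d. encounters from a latent
  diagnosis-category mixture with the conditional rates the analysis
  assumes (per-category F-criterion rates, per-organism urine/blood
  accordance probabilities, log-normal PCT mixtures by bacteraemia
  status), for parameter-recovery and power-style experiments.

:func:`check_constraints` audits a cohort against the ledger with counting
code independent of the builder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .micro import (
    Accordance,
    BacteraemiaStatus,
    UrineStatusValue,
    classify_urine_culture,
)
from .model import (
    AltFocus,
    BloodCultureSet,
    CollectionMethod,
    DiagnosisCategory,
    Encounter,
    GUSymptom,
    Isolate,
    OrganDysfunction,
    Sex,
    UrineCulture,
)
from .scoring import (
    PCT_CUTOFF_NG_ML,
    classify_encounter,
    compute_triple_f,
)
from .vocab import DEFAULT_VOCABULARY

E_COLI = "Escherichia coli"
S_AUREUS = "Staphylococcus aureus"

_ORGAN_CYCLE = [
    OrganDysfunction.KIDNEY,
    OrganDysfunction.CIRCULATION,
    OrganDysfunction.BRAIN,
    OrganDysfunction.FUNCTIONAL_DECLINE_ELDERLY,
    OrganDysfunction.GI_TRACT,
    OrganDysfunction.HEART,
    OrganDysfunction.METABOLISM,
    OrganDysfunction.LIVER,
]

# analyzable ages cycle to a median of 73 years
_AGE_CYCLE = [59, 66, 73, 80, 87]


# --------------------------------------------------------------------------
# constraint ledger
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Constraint:
    name: str
    value: int
    hard: bool = True


class CohortConstraints:
    """Named integer constraints with hardness flags."""

    def __init__(self, constraints: Iterable[Constraint]):
        self._by_name = {c.name: c for c in constraints}

    def __getitem__(self, name: str) -> int:
        return self._by_name[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def is_hard(self, name: str) -> bool:
        return self._by_name[name].hard

    def names(self) -> list[str]:
        return list(self._by_name)

    def audit(self) -> list[str]:
        """Arithmetic consistency of the hard constraints; [] when clean."""
        c = self
        problems = []

        def expect(desc: str, lhs: int, rhs: int):
            if lhs != rhs:
                problems.append(f"{desc}: {lhs} != {rhs}")

        expect("screened = sterile + contaminated + analyzed",
               c["n_screened"],
               c["n_sterile"] + c["n_contaminated"] + c["n_analyzed"])
        dx_sum = sum(
            c[f"dx_{k}"]
            for k in ("bacteremic", "probable", "possible", "urocystitis",
                      "abu", "sa_alt_focus")
        )
        expect("diagnosis partition sums to analyzed", dx_sum, c["n_analyzed"])
        expect("true bacteraemia = accordant + discordant",
               c["true_bacteraemia"], c["accordant"] + c["discordant"])
        for f in ("f1", "f2"):
            joint = sum(
                c[f"{f}_{k}"]
                for k in ("bacteremic", "probable", "possible", "urocystitis",
                          "abu", "sa_alt_focus")
            )
            expect(f"{f} joint cells sum to marginal", joint, c[f"{f}_total"])
        expect("alternative-focus split sums to total",
               c["alt_focus_total"],
               c["dx_sa_alt_focus"] + c["possible_with_focus"]
               + c["abu_with_focus"])
        expect("focus labels sum to total",
               c["alt_focus_total"],
               c["focus_pneumonia"] + c["focus_port"] + c["focus_ssti"]
               + c["focus_influenza"] + c["focus_other"])
        for name in ("pct_below_01", "pct_below_025_and_score0",
                     "bact_below_025"):
            if c[name] > c["pct_below_025"]:
                problems.append(f"{name} exceeds pct_below_025")
        if c["accordant_below_025"] > c["bact_below_025"]:
            problems.append("accordant_below_025 exceeds bact_below_025")
        return problems


def default_constraints() -> CohortConstraints:
    """The printed ledger with the canonical resolution of the in-source
    inconsistencies (possible SUTI 51 / ABU 56; focus split 20/42; the two
    category-level F3 cells that clash with the rule definitions are soft).
    """
    hard = Constraint
    soft = lambda n, v: Constraint(n, v, hard=False)  # noqa: E731
    return CohortConstraints([
        hard("n_screened", 403),
        hard("n_sterile", 138),
        hard("n_contaminated", 82),
        hard("n_analyzed", 183),
        hard("dx_bacteremic", 44),
        hard("dx_probable", 26),
        hard("dx_possible", 51),
        hard("dx_urocystitis", 1),
        hard("dx_abu", 56),
        hard("dx_sa_alt_focus", 5),
        hard("f1_total", 140),
        hard("f2_total", 115),
        hard("f3_total", 54),
        hard("f1_bacteremic", 38),
        hard("f2_bacteremic", 31),
        hard("f3_bacteremic", 20),
        hard("f1_probable", 24),
        hard("f2_probable", 17),
        # probable SUTI requires GU symptoms by definition, so all 26 carry
        # F3; the printed 25 is kept as a soft cell.
        soft("f3_probable", 25),
        hard("f1_possible", 44),
        hard("f2_possible", 33),
        # with F3 marginal 54 fixed, the possible-SUTI F3 cell is 6 (the
        # printed 7 sits on the inconsistent n=52 row).
        soft("f3_possible", 7),
        hard("f1_urocystitis", 0),
        hard("f2_urocystitis", 0),
        hard("f3_urocystitis", 1),
        hard("f1_abu", 32),
        hard("f2_abu", 29),
        hard("f3_abu", 0),
        hard("f1_sa_alt_focus", 2),
        hard("f2_sa_alt_focus", 5),
        hard("f3_sa_alt_focus", 1),
        hard("score0", 14),
        hard("pct_below_025", 53),
        hard("pct_below_025_and_score0", 6),
        hard("pct_below_01", 34),
        hard("true_bacteraemia", 65),
        hard("accordant", 49),
        hard("discordant", 16),
        hard("bact_below_025", 6),
        hard("accordant_below_025", 2),
        hard("alt_focus_total", 67),
        hard("focus_pneumonia", 30),
        hard("focus_port", 9),
        hard("focus_ssti", 9),
        hard("focus_influenza", 4),
        hard("focus_other", 15),
        hard("possible_with_focus", 20),
        hard("abu_with_focus", 42),
        hard("ecoli_urine", 94),
        hard("mixed_urine", 32),
        hard("female", 91),
    ])


# --------------------------------------------------------------------------
# deterministic fixture builder
# --------------------------------------------------------------------------

@dataclass
class _Plan:
    """Raw-field plan for one analyzable encounter."""

    f1: bool = False
    f2: bool = False
    gu: set = field(default_factory=set)
    pct: float = 1.0
    urine: list = field(default_factory=list)
    blood_species: str | None = None
    documented: AltFocus = AltFocus.NONE
    mrsa: bool | None = None


class InfeasibleConstraints(ValueError):
    pass


def _need(condition: bool, what: str):
    if not condition:
        raise InfeasibleConstraints(f"infeasible constraint set: {what}")


def _mixed(primary: str, cfu: float = 1e5) -> list[Isolate]:
    secondary = ("Proteus mirabilis"
                 if primary == "Enterococcus faecalis"
                 else "Enterococcus faecalis")
    return [Isolate(primary, cfu), Isolate(secondary, 1e4)]


def _pure(species: str, cfu: float = 1e5) -> list[Isolate]:
    return [Isolate(species, cfu)]


def build_fixture_cohort(
    constraints: CohortConstraints | None = None, seed: int = 0
) -> list[Encounter]:
    """Build the 403-record fixture cohort (raw fields only).

    Raises :class:`InfeasibleConstraints` when the ledger is internally
    inconsistent or the fixed assignment layout cannot realize it.
    """
    c = constraints if constraints is not None else default_constraints()
    problems = c.audit()
    if problems:
        raise InfeasibleConstraints("; ".join(problems))

    plans: list[_Plan] = []

    n_bact = c["dx_bacteremic"]
    n_prob = c["dx_probable"]
    n_poss = c["dx_possible"]
    n_uro = c["dx_urocystitis"]
    n_abu = c["dx_abu"]
    n_sa = c["dx_sa_alt_focus"]

    # --- bacteremic SUTI: accordant non-staphylococcal bacteraemia -------
    f3_bact = c["f3_bacteremic"]
    n_mixed_bact = 6          # two urine pathogens, one of them in blood
    ecoli_bact = c["f1_bacteremic"]  # 38 E. coli bacteraemias by layout
    acc_below = c["accordant_below_025"]
    others = ["Klebsiella pneumoniae", "Klebsiella pneumoniae",
              "Proteus mirabilis", "Pseudomonas aeruginosa",
              "Enterococcus faecalis", "Enterococcus faecalis"]
    _need(n_bact - ecoli_bact <= len(others), "non-E.coli bacteremic slots")
    for i in range(n_bact):
        primary = E_COLI if i < ecoli_bact else others[i - ecoli_bact]
        p = _Plan(
            f1=i < c["f1_bacteremic"],
            f2=i >= n_bact - c["f2_bacteremic"],
            gu=({GUSymptom.FLANK_PAIN} if i % 2 == 0 else {GUSymptom.DYSURIA})
            if i < f3_bact else set(),
            pct=0.15 if i >= n_bact - acc_below else 2.0,
            urine=_mixed(primary) if i < n_mixed_bact else _pure(primary),
            blood_species=primary,
        )
        plans.append(p)

    # --- probable SUTI: GU symptoms + clinical systemic reaction ---------
    prob_below = 13           # free PCT<0.25 slots allotted to this group
    for i in range(n_prob):
        plans.append(_Plan(
            f1=i < c["f1_probable"],
            f2=i >= n_prob - c["f2_probable"],
            gu={GUSymptom.DYSURIA} if i % 2 else {GUSymptom.FLANK_PAIN},
            pct=0.05 if i < prob_below else 1.0,
            urine=(_mixed(E_COLI) if i < 6
                   else _pure(E_COLI) if i < 20
                   else _pure(["Klebsiella pneumoniae", "Klebsiella pneumoniae",
                               "Proteus mirabilis", "Proteus mirabilis",
                               "Enterococcus faecalis",
                               "Enterococcus faecalis"][i - 20])),
        ))

    # --- possible SUTI ----------------------------------------------------
    # branch 1 (documented focus + GU symptoms): F3 cell derived from the
    # hard F3 marginal; branch 2 (no GU symptoms) holds 14 discordant
    # bacteraemias that establish a focus via the bloodstream organism.
    f3_poss = (c["f3_total"] - c["f3_bacteremic"] - n_prob
               - c["f3_urocystitis"] - c["f3_abu"] - c["f3_sa_alt_focus"])
    _need(0 <= f3_poss <= n_poss, "possible-SUTI F3 cell")
    n_disc_poss = c["possible_with_focus"] - f3_poss
    _need(0 <= n_disc_poss <= c["discordant"], "discordant slots in possible")
    disc_lo, disc_hi = f3_poss, f3_poss + n_disc_poss
    branch1_focus = [AltFocus.PNEUMONIA] * 4 + [AltFocus.INFLUENZA] * 2
    _need(f3_poss <= len(branch1_focus), "possible branch-1 focus labels")
    poss_below_disc = 2       # discordant bacteraemias under the PCT cutoff
    for i in range(n_poss):
        discordant = disc_lo <= i < disc_hi
        if discordant:
            pct = 0.15 if i < disc_lo + poss_below_disc else 2.0
        elif disc_hi <= i < disc_hi + 14:
            pct = 0.05
        else:
            pct = 1.0
        if discordant:
            urine = _pure(E_COLI)
        elif disc_hi <= i < disc_hi + 10:
            urine = _mixed(E_COLI)
        elif i < f3_poss:
            urine = _pure("Klebsiella pneumoniae")
        else:
            urine = _pure(["Enterococcus faecalis", "Proteus mirabilis",
                           "Morganella morganii",
                           "Staphylococcus saprophyticus",
                           "Enterobacter cloacae",
                           "Klebsiella oxytoca"][i % 6])
        plans.append(_Plan(
            f1=i < c["f1_possible"],
            f2=i >= n_poss - c["f2_possible"],
            gu={GUSymptom.DYSURIA} if i < f3_poss else set(),
            pct=pct,
            urine=urine,
            blood_species=("Streptococcus pneumoniae" if i % 2 == 0
                           else "Streptococcus pyogenes")
            if discordant else None,
            documented=branch1_focus[i] if i < f3_poss else AltFocus.NONE,
        ))

    # --- urocystitis ------------------------------------------------------
    for _ in range(n_uro):
        plans.append(_Plan(gu={GUSymptom.DYSURIA}, pct=0.05,
                           urine=_pure(E_COLI)))

    # --- ABU --------------------------------------------------------------
    n_abu_focus = c["abu_with_focus"]
    _need(n_abu_focus <= n_abu, "ABU focus split")
    n_disc_abu = c["discordant"] - n_disc_poss
    _need(0 <= n_disc_abu <= n_abu_focus, "discordant slots in ABU")
    abu_focus_labels = ([AltFocus.PNEUMONIA] * 26 + [AltFocus.PORT_INFECTION] * 7
                        + [AltFocus.SSTI] * 7 + [AltFocus.INFLUENZA] * 2)
    _need(n_abu_focus <= len(abu_focus_labels), "ABU focus labels")
    abu_nofocus_below = (c["pct_below_025_and_score0"]
                         - 0)  # all score-0 encounters live in this group
    abu_focus_below = 13      # free PCT<0.25 slots allotted to this group
    for i in range(n_abu):
        with_focus = i < n_abu_focus
        discordant = i < n_disc_abu
        if with_focus:
            pct = 0.15 if i < n_disc_abu + abu_focus_below else 1.0
        else:
            j = i - n_abu_focus
            pct = 0.05 if j < abu_nofocus_below else 1.0
        if discordant:
            urine = _pure("Enterococcus faecalis")
        elif n_disc_abu <= i < n_disc_abu + 10:
            urine = _mixed(E_COLI)
        elif n_disc_abu + 10 <= i < n_disc_abu + 11:
            urine = _pure(E_COLI)
        else:
            urine = _pure(["Enterococcus faecium", "Enterococcus faecalis",
                           "Klebsiella pneumoniae", "Proteus mirabilis",
                           "Citrobacter koseri", "Morganella morganii"][i % 6])
        plans.append(_Plan(
            f1=with_focus and i < c["f1_abu"],
            f2=with_focus and i >= n_abu_focus - c["f2_abu"],
            pct=pct,
            urine=urine,
            blood_species="Streptococcus pneumoniae" if discordant else None,
            documented=abu_focus_labels[i] if with_focus else AltFocus.NONE,
        ))

    # --- S. aureus bacteraemia with bacteriuria ---------------------------
    sa_focus = [AltFocus.PORT_INFECTION, AltFocus.PORT_INFECTION,
                AltFocus.SSTI, AltFocus.SSTI, AltFocus.OTHER]
    for i in range(n_sa):
        plans.append(_Plan(
            f1=i < c["f1_sa_alt_focus"],
            f2=i < c["f2_sa_alt_focus"],
            gu={GUSymptom.DYSURIA} if i < c["f3_sa_alt_focus"] else set(),
            pct=2.0,
            urine=[Isolate(S_AUREUS, 1e5, methicillin_resistant=(i == 0))],
            blood_species=S_AUREUS,
            documented=sa_focus[i % len(sa_focus)],
            mrsa=(i == 0),
        ))

    _need(len(plans) == c["n_analyzed"], "analyzable group sizes")

    # --- materialize analyzable encounters --------------------------------
    methods = [CollectionMethod.MIDSTREAM, CollectionMethod.MIDSTREAM,
               CollectionMethod.SINGLE_CATHETER,
               CollectionMethod.INDWELLING_AT_REPLACEMENT]
    n_female = c["female"]
    encounters: list[Encounter] = []
    for k, p in enumerate(plans):
        organs = {_ORGAN_CYCLE[k % len(_ORGAN_CYCLE)]} if p.f2 else set()
        if p.blood_species is None:
            bc_sets = [BloodCultureSet("B1"), BloodCultureSet("B2")]
        else:
            iso = Isolate(p.blood_species, methicillin_resistant=p.mrsa)
            bc_sets = [BloodCultureSet("B1", [iso]), BloodCultureSet("B2")]
        encounters.append(Encounter(
            encounter_id="",  # assigned after shuffling
            age_years=_AGE_CYCLE[k % len(_AGE_CYCLE)],
            sex=Sex.FEMALE if k < n_female else Sex.MALE,
            fever_at_triage=p.f1,
            chills_or_rigors_reported=False,
            organ_dysfunctions=organs,
            gu_symptoms=p.gu,
            pct_ng_ml=p.pct,
            urine_culture=UrineCulture(methods[k % len(methods)],
                                       list(p.urine)),
            blood_culture_sets=bc_sets,
            urinary_catheter=(k % 7 == 0),
            documented_alt_focus=p.documented,
        ))

    # --- excluded records: sterile and contaminated urine cultures -------
    excluded: list[Encounter] = []
    n_sterile, n_contam = c["n_sterile"], c["n_contaminated"]
    for k in range(n_sterile + n_contam):
        if k < n_sterile:
            isolates: list[Isolate] = []
        elif k < n_sterile + 40:   # flora-only growth
            isolates = [Isolate("Lactobacillus crispatus", 1e4),
                        Isolate("Corynebacterium amycolatum", 1e4)]
        elif k < n_sterile + 62:   # > 2 pathogenic species
            isolates = [Isolate(E_COLI, 1e4),
                        Isolate("Klebsiella pneumoniae", 1e4),
                        Isolate("Proteus mirabilis", 1e4)]
        else:                      # pathogens below the CFU threshold
            isolates = [Isolate(E_COLI, 500)]
        excluded.append(Encounter(
            encounter_id="",
            age_years=[49, 62, 71, 83][k % 4],
            sex=Sex.FEMALE if k % 2 == 0 else Sex.MALE,
            fever_at_triage=(k % 3 == 0),
            chills_or_rigors_reported=False,
            organ_dysfunctions={_ORGAN_CYCLE[k % len(_ORGAN_CYCLE)]}
            if k % 2 == 0 else set(),
            gu_symptoms=set(),
            pct_ng_ml=0.5,
            urine_culture=UrineCulture(methods[k % len(methods)], isolates),
            blood_culture_sets=[BloodCultureSet("B1"), BloodCultureSet("B2")],
            documented_alt_focus=AltFocus.NONE,
        ))

    cohort = encounters + excluded
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    cohort = [cohort[i] for i in order]
    for idx, enc in enumerate(cohort, start=1):
        enc.encounter_id = f"E{idx:04d}"
    return cohort


# --------------------------------------------------------------------------
# constraint checker (counting logic independent of the builder)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintCheck:
    name: str
    expected: int
    observed: int
    hard: bool

    @property
    def satisfied(self) -> bool:
        return self.expected == self.observed


@dataclass(frozen=True)
class ConstraintReport:
    checks: list[ConstraintCheck]

    @property
    def hard_violations(self) -> list[ConstraintCheck]:
        return [c for c in self.checks if c.hard and not c.satisfied]

    @property
    def ok(self) -> bool:
        return not self.hard_violations


def check_constraints(
    cohort: Sequence[Encounter],
    constraints: CohortConstraints | None = None,
    pct_cutoff_ng_ml: float = PCT_CUTOFF_NG_ML,
) -> ConstraintReport:
    """Re-derive every ledger quantity from the raw cohort and compare."""
    c = constraints if constraints is not None else default_constraints()

    sterile = contaminated = 0
    analyzable: list[Encounter] = []
    for enc in cohort:
        status = classify_urine_culture(enc.urine_culture).status
        if status is UrineStatusValue.STERILE:
            sterile += 1
        elif status is UrineStatusValue.CONTAMINATED:
            contaminated += 1
        else:
            analyzable.append(enc)

    results = [classify_encounter(enc, pct_cutoff_ng_ml=pct_cutoff_ng_ml)
               for enc in analyzable]

    obs: dict[str, int] = {
        "n_screened": len(cohort),
        "n_sterile": sterile,
        "n_contaminated": contaminated,
        "n_analyzed": len(analyzable),
    }
    cat_key = {
        DiagnosisCategory.BACTEREMIC_SUTI: "bacteremic",
        DiagnosisCategory.PROBABLE_SUTI: "probable",
        DiagnosisCategory.POSSIBLE_SUTI: "possible",
        DiagnosisCategory.UROCYSTITIS: "urocystitis",
        DiagnosisCategory.ABU: "abu",
        DiagnosisCategory.SA_ALT_FOCUS: "sa_alt_focus",
    }
    for key in cat_key.values():
        obs[f"dx_{key}"] = 0
        for f in ("f1", "f2", "f3"):
            obs[f"{f}_{key}"] = 0
    for f in ("f1", "f2", "f3"):
        obs[f"{f}_total"] = 0
    obs.update({
        "score0": 0, "pct_below_025": 0, "pct_below_025_and_score0": 0,
        "pct_below_01": 0, "true_bacteraemia": 0, "accordant": 0,
        "discordant": 0, "bact_below_025": 0, "accordant_below_025": 0,
        "alt_focus_total": 0, "focus_pneumonia": 0, "focus_port": 0,
        "focus_ssti": 0, "focus_influenza": 0, "focus_other": 0,
        "possible_with_focus": 0, "abu_with_focus": 0,
        "ecoli_urine": 0, "mixed_urine": 0, "female": 0,
    })
    focus_key = {
        "pneumonia": "focus_pneumonia",
        "port_infection": "focus_port",
        "ssti": "focus_ssti",
        "influenza": "focus_influenza",
    }
    for enc, res in zip(analyzable, results):
        key = cat_key[res.category]
        obs[f"dx_{key}"] += 1
        tf = res.triple_f
        for f, flag in (("f1", tf.f1), ("f2", tf.f2), ("f3", tf.f3)):
            if flag:
                obs[f"{f}_{key}"] += 1
                obs[f"{f}_total"] += 1
        below = enc.pct_ng_ml < pct_cutoff_ng_ml
        if tf.score == 0:
            obs["score0"] += 1
            if below:
                obs["pct_below_025_and_score0"] += 1
        if below:
            obs["pct_below_025"] += 1
        if enc.pct_ng_ml < 0.1:
            obs["pct_below_01"] += 1
        bact = res.bacteraemia.status is BacteraemiaStatus.TRUE_BACTERAEMIA
        if bact:
            obs["true_bacteraemia"] += 1
            if below:
                obs["bact_below_025"] += 1
            if res.bacteraemia.accordance is Accordance.ACCORDANT:
                obs["accordant"] += 1
                if below:
                    obs["accordant_below_025"] += 1
            elif res.bacteraemia.accordance is Accordance.DISCORDANT:
                obs["discordant"] += 1
        if res.alternative_focus_present:
            obs["alt_focus_total"] += 1
            obs[focus_key.get(res.alternative_focus_label, "focus_other")] += 1
            if res.category is DiagnosisCategory.POSSIBLE_SUTI:
                obs["possible_with_focus"] += 1
            elif res.category is DiagnosisCategory.ABU:
                obs["abu_with_focus"] += 1
        if any(i.species == E_COLI for i in res.urine.significant_isolates):
            obs["ecoli_urine"] += 1
        if len(res.urine.significant_isolates) == 2:
            obs["mixed_urine"] += 1
        if enc.sex is Sex.FEMALE:
            obs["female"] += 1

    checks = [
        ConstraintCheck(name, c[name], obs.get(name, 0), c.is_hard(name))
        for name in c.names()
    ]
    return ConstraintReport(checks)


# --------------------------------------------------------------------------
# stochastic sampler
# --------------------------------------------------------------------------

_DEFAULT_DX_PROBS = {
    "bacteremic": 44 / 183,
    "probable": 26 / 183,
    "possible": 51 / 183,
    "urocystitis": 1 / 183,
    "abu": 56 / 183,
    "sa_alt_focus": 5 / 183,
}

# per-category (F1, F2, F3) conditional rates
_DEFAULT_F_RATES = {
    "bacteremic": (0.864, 0.705, 0.455),
    "probable": (0.923, 0.654, 0.962),
    "possible": (0.846, 0.635, 0.135),
    "urocystitis": (0.0, 0.0, 1.0),
    "abu": (0.582, 0.527, 0.0),
    "sa_alt_focus": (0.4, 1.0, 0.2),
}

_DEFAULT_ALT_FOCUS_RATES = {
    "bacteremic": 0.0, "probable": 0.0, "possible": 0.404,
    "urocystitis": 0.0, "abu": 0.745, "sa_alt_focus": 1.0,
}

_DEFAULT_FOCUS_LABELS = {
    AltFocus.PNEUMONIA: 30 / 67,
    AltFocus.PORT_INFECTION: 9 / 67,
    AltFocus.SSTI: 9 / 67,
    AltFocus.INFLUENZA: 4 / 67,
    AltFocus.OTHER: 15 / 67,
}

_DEFAULT_ORGANISM_FREQS = {
    "Escherichia coli": 0.514,
    "Enterococcus faecalis": 0.12,
    "Klebsiella pneumoniae": 0.10,
    "Proteus mirabilis": 0.06,
    "Pseudomonas aeruginosa": 0.05,
    "Enterococcus faecium": 0.04,
    "Morganella morganii": 0.03,
    "Enterobacter cloacae": 0.03,
    "Staphylococcus saprophyticus": 0.03,
    "Citrobacter koseri": 0.016,
    "Serratia marcescens": 0.01,
}

_DEFAULT_ACCORDANCE = {
    "Escherichia coli": 0.853,
    "Proteus mirabilis": 0.60,
    "Klebsiella pneumoniae": 0.50,
    "Pseudomonas aeruginosa": 0.50,
    "Enterococcus faecalis": 0.167,
    "Enterococcus faecium": 0.0,
}


@dataclass(frozen=True)
class GenerativeParams:
    """Conditional rates for the stochastic cohort generator.

    PCT is drawn from a log-normal mixture keyed on bacteraemia: medians
    of 2.0 ng/mL (bacteremic) and 0.37 ng/mL (non-bacteremic) with a log
    scale of 1.5, giving roughly the dichotomized fractions the analysis
    assumes (about 9% of bacteremic and 40% of non-bacteremic encounters
    below the 0.25 ng/mL cutoff).
    """

    diagnosis_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DX_PROBS))
    f_rates: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_F_RATES))
    alt_focus_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ALT_FOCUS_RATES))
    focus_label_probs: Mapping[AltFocus, float] = field(
        default_factory=lambda: dict(_DEFAULT_FOCUS_LABELS))
    organism_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ORGANISM_FREQS))
    accordance_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ACCORDANCE))
    default_accordance: float = 0.5
    mixed_culture_prob: float = 0.175
    pct_logmedian_bacteremic: float = math.log(2.0)
    pct_logmedian_other: float = math.log(0.37)
    pct_logsd: float = 1.5
    female_prob: float = 0.5

    def validate(self) -> None:
        for name, dist in (
            ("diagnosis_probs", self.diagnosis_probs),
            ("focus_label_probs", self.focus_label_probs),
            ("organism_freqs", self.organism_freqs),
        ):
            vals = list(dist.values())
            if any(v < 0 or v > 1 for v in vals):
                raise ValueError(f"{name}: probabilities must lie in [0,1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{name}: probabilities must sum to 1")
        for rates in self.f_rates.values():
            if any(r < 0 or r > 1 for r in rates):
                raise ValueError("f_rates must lie in [0,1]")
        for p in list(self.alt_focus_rates.values()) + list(
                self.accordance_probs.values()):
            if p < 0 or p > 1:
                raise ValueError("rates must lie in [0,1]")


@dataclass
class SampledCohort:
    encounters: list[Encounter]
    latent: "object"  # pandas.DataFrame of generator-side labels


def sample_cohort(
    params: GenerativeParams | None = None,
    n: int = 183,
    seed: int = 0,
) -> SampledCohort:
    """Draw ``n`` independent encounters from the generative mixture.

    Only raw fields are written; the pipeline re-derives all labels.  The
    returned ``latent`` frame records the generator-side category, urine
    organism and accordance draw for parameter-recovery checks.
    """
    import pandas as pd

    p = params if params is not None else GenerativeParams()
    p.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    categories = list(p.diagnosis_probs)
    cat_probs = np.array([p.diagnosis_probs[k] for k in categories])
    organisms = list(p.organism_freqs)
    org_probs = np.array([p.organism_freqs[k] for k in organisms])
    focus_labels = list(p.focus_label_probs)
    focus_probs = np.array([p.focus_label_probs[k] for k in focus_labels])

    encounters: list[Encounter] = []
    latent_rows = []
    for i in range(n):
        cat = categories[rng.choice(len(categories), p=cat_probs)]
        r1, r2, r3 = p.f_rates[cat]
        f1, f2, f3 = (rng.random() < r1, rng.random() < r2, rng.random() < r3)
        if cat == "sa_alt_focus":
            urine = [Isolate(S_AUREUS, 1e5,
                             methicillin_resistant=bool(rng.random() < 0.1))]
            primary = S_AUREUS
        else:
            primary = organisms[rng.choice(len(organisms), p=org_probs)]
            if rng.random() < p.mixed_culture_prob:
                urine = _mixed(primary)
            else:
                urine = _pure(primary)

        accordant_draw = None
        blood_species = None
        if cat == "sa_alt_focus":
            blood_species = S_AUREUS
            accordant_draw = True
        elif cat == "bacteremic":
            p_acc = p.accordance_probs.get(primary, p.default_accordance)
            accordant_draw = bool(rng.random() < p_acc)
            blood_species = (primary if accordant_draw
                             else "Streptococcus pneumoniae")
        bacteremic = blood_species is not None

        mu = (p.pct_logmedian_bacteremic if bacteremic
              else p.pct_logmedian_other)
        pct = float(np.exp(rng.normal(mu, p.pct_logsd)))

        documented = AltFocus.NONE
        if rng.random() < p.alt_focus_rates.get(cat, 0.0):
            documented = focus_labels[rng.choice(len(focus_labels),
                                                 p=focus_probs)]

        if f3:
            gu = ({GUSymptom.DYSURIA} if rng.random() < 0.6
                  else {GUSymptom.FLANK_PAIN})
        else:
            gu = set()
        organs = ({_ORGAN_CYCLE[int(rng.integers(len(_ORGAN_CYCLE)))]}
                  if f2 else set())
        if blood_species is None:
            bc_sets = [BloodCultureSet("B1"), BloodCultureSet("B2")]
        else:
            bc_sets = [BloodCultureSet("B1", [Isolate(blood_species)]),
                       BloodCultureSet("B2")]

        encounters.append(Encounter(
            encounter_id=f"S{i + 1:05d}",
            age_years=float(np.clip(rng.normal(72, 12), 18, 101)),
            sex=Sex.FEMALE if rng.random() < p.female_prob else Sex.MALE,
            fever_at_triage=f1,
            chills_or_rigors_reported=False,
            organ_dysfunctions=organs,
            gu_symptoms=gu,
            pct_ng_ml=round(pct, 3),
            urine_culture=UrineCulture(CollectionMethod.MIDSTREAM,
                                       list(urine)),
            blood_culture_sets=bc_sets,
            documented_alt_focus=documented,
        ))
        latent_rows.append({
            "latent_category": cat,
            "f1": f1, "f2": f2, "f3": f3,
            "urine_primary": primary,
            "bacteremic": bacteremic,
            "accordant": accordant_draw,
        })
    return SampledCohort(encounters, pd.DataFrame(latent_rows))
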