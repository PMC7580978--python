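"""End-to-end orchestration: filter -> score -> classify -> evaluate.

:func:`run_pipeline` runs the whole analysis on a cohort (a file, the
built-in fixture, or a simulated sample) and returns a consolidated report:
the per-encounter classification table with rule traces, the diagnosis-by-
F-criterion cross table, the PCT diagnostic-accuracy report for any and for
accordant bacteraemia, the stewardship impact at both treatment thresholds,
and — when the input is the fixture — the constraint-check summary.  With
an output directory set, all tables are written as CSV plus a markdown
summary and a run manifest; outputs are deterministic for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .dta import DTAReport, TwoByTwo, build_two_by_two, cohens_kappa, dta_metrics
from .io import read_cohort, write_cohort
from .micro import Accordance, BacteraemiaStatus, UrineStatusValue, classify_urine_culture
from .model import DiagnosisCategory, Encounter, Sex
from .scoring import (
    PCT_CUTOFF_NG_ML,
    ClassificationResult,
    classify_encounter,
    compute_triple_f,
    recommend_workup,
)
from .stewardship import (
    ABSImpactReport,
    BCAvoidanceReport,
    TreatmentThreshold,
    simulate_abs_impact,
    simulate_bc_avoidance,
)
from .synthetic import (
    ConstraintReport,
    GenerativeParams,
    build_fixture_cohort,
    check_constraints,
    default_constraints,
    sample_cohort,
)

logger = logging.getLogger(__name__)

_CATEGORY_ORDER = [
    DiagnosisCategory.BACTEREMIC_SUTI,
    DiagnosisCategory.PROBABLE_SUTI,
    DiagnosisCategory.POSSIBLE_SUTI,
    DiagnosisCategory.UROCYSTITIS,
    DiagnosisCategory.ABU,
    DiagnosisCategory.SA_ALT_FOCUS,
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    source: str = "fixture"          # "fixture" | "file" | "simulate"
    input_path: str | None = None    # for source="file"
    n_simulate: int = 183            # for source="simulate"
    pct_cutoff_ng_ml: float = PCT_CUTOFF_NG_ML
    cfu_threshold: float = 1_000.0
    ci_level: float = 0.95
    ci_method: str = "beta"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.pct_cutoff_ng_ml <= 0 or self.cfu_threshold <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.source == "file" and not self.input_path:
            raise ValueError("source='file' requires input_path")


@dataclass
class PipelineReport:
    config: RunConfig
    n_screened: int
    n_sterile: int
    n_contaminated: int
    classification: pd.DataFrame
    cross_table: pd.DataFrame
    dta_any: DTAReport | None
    dta_accordant: DTAReport | None
    two_by_two_any: TwoByTwo | None
    two_by_two_accordant: TwoByTwo | None
    bc_avoidance: BCAvoidanceReport
    abs_possible: ABSImpactReport
    abs_probable: ABSImpactReport
    constraint_report: ConstraintReport | None = None

    @property
    def n_analyzed(self) -> int:
        return len(self.classification)


def classification_table(
    encounters: Sequence[Encounter],
    results: Sequence[ClassificationResult],
    pct_cutoff_ng_ml: float = PCT_CUTOFF_NG_ML,
) -> pd.DataFrame:
    """One row per analyzable encounter with scores, labels and rule trace."""
    rows = []
    for enc, res in zip(encounters, results):
        tf = res.triple_f
        rows.append({
            "encounter_id": enc.encounter_id,
            "age_years": enc.age_years,
            "sex": enc.sex.value,
            "f1": int(tf.f1),
            "f2": int(tf.f2),
            "f3": int(tf.f3),
            "triple_f_score": tf.score,
            "pct_ng_ml": enc.pct_ng_ml,
            "pct_at_or_above_cutoff": int(enc.pct_ng_ml >= pct_cutoff_ng_ml),
            "urine_organisms": ";".join(res.urine.organisms),
            "bacteraemia": res.bacteraemia.status.value,
            "accordance": res.bacteraemia.accordance.value,
            "dominant_uropathogen": res.bacteraemia.dominant_uropathogen or "",
            "systemic_features": int(res.systemic_features),
            "alternative_focus": res.alternative_focus_label or "",
            "category": res.category.value,
            "workup": recommend_workup(tf, enc.pct_ng_ml,
                                       pct_cutoff_ng_ml).value,
            "rationale": "|".join(res.rationale),
        })
    return pd.DataFrame(rows)


def diagnosis_cross_table(
    results: Sequence[ClassificationResult],
) -> pd.DataFrame:
    """Diagnosis-by-F-criterion cross: counts of F1/F2/F3 and alternative
    focus per category (the 3F distribution summary)."""
    rows = []
    for cat in _CATEGORY_ORDER:
        sub = [r for r in results if r.category is cat]
        rows.append({
            "category": cat.value,
            "n": len(sub),
            "f1": sum(r.triple_f.f1 for r in sub),
            "f2": sum(r.triple_f.f2 for r in sub),
            "f3": sum(r.triple_f.f3 for r in sub),
            "alt_focus": sum(r.alternative_focus_present for r in sub),
        })
    return pd.DataFrame(rows)


def pct_accuracy(
    encounters: Sequence[Encounter],
    results: Sequence[ClassificationResult],
    pct_cutoff_ng_ml: float = PCT_CUTOFF_NG_ML,
    ci_level: float = 0.95,
    ci_method: str = "beta",
) -> tuple[TwoByTwo, DTAReport, TwoByTwo, DTAReport]:
    """PCT dichotomization vs any / accordant true bacteraemia."""
    test = [e.pct_ng_ml >= pct_cutoff_ng_ml for e in encounters]
    any_bact = [
        r.bacteraemia.status is BacteraemiaStatus.TRUE_BACTERAEMIA
        for r in results
    ]
    accordant = [
        r.bacteraemia.accordance is Accordance.ACCORDANT for r in results
    ]
    t_any = build_two_by_two(test, any_bact)
    t_acc = build_two_by_two(test, accordant)
    rep_any = dataclasses.replace(
        dta_metrics(t_any, ci_level, ci_method),
        kappa=cohens_kappa(t_any, ci_level),
    )
    rep_acc = dataclasses.replace(
        dta_metrics(t_acc, ci_level, ci_method),
        kappa=cohens_kappa(t_acc, ci_level),
    )
    return t_any, rep_any, t_acc, rep_acc


def _dta_frame(name: str, t: TwoByTwo, rep: DTAReport) -> pd.DataFrame:
    def row(metric, est):
        return {
            "condition": name, "metric": metric, "value": est.value,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
        }
    return pd.DataFrame([
        {"condition": name, "metric": "tp", "value": t.tp,
         "ci_low": None, "ci_high": None},
        {"condition": name, "metric": "fp", "value": t.fp,
         "ci_low": None, "ci_high": None},
        {"condition": name, "metric": "fn", "value": t.fn,
         "ci_low": None, "ci_high": None},
        {"condition": name, "metric": "tn", "value": t.tn,
         "ci_low": None, "ci_high": None},
        row("sensitivity", rep.sensitivity),
        row("specificity", rep.specificity),
        row("ppv", rep.ppv),
        row("npv", rep.npv),
        {"condition": name, "metric": "youden_j", "value": rep.youden_j,
         "ci_low": None, "ci_high": None},
        row("kappa", rep.kappa),
    ])


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full analysis described in the module docstring."""
    if config.source == "fixture":
        cohort = build_fixture_cohort(seed=config.seed)
    elif config.source == "file":
        cohort = read_cohort(config.input_path)
    elif config.source == "simulate":
        cohort = sample_cohort(GenerativeParams(), config.n_simulate,
                               config.seed).encounters
    else:
        raise ValueError(f"unknown source {config.source!r}")
    logger.info("screened %d encounters", len(cohort))

    sterile = contaminated = 0
    analyzable: list[Encounter] = []
    for enc in cohort:
        status = classify_urine_culture(
            enc.urine_culture, cfu_threshold=config.cfu_threshold
        ).status
        if status is UrineStatusValue.STERILE:
            sterile += 1
        elif status is UrineStatusValue.CONTAMINATED:
            contaminated += 1
        else:
            analyzable.append(enc)
    logger.info(
        "excluded %d sterile and %d contaminated; %d analyzable",
        sterile, contaminated, len(analyzable),
    )

    results = [
        classify_encounter(
            enc,
            cfu_threshold=config.cfu_threshold,
            pct_cutoff_ng_ml=config.pct_cutoff_ng_ml,
        )
        for enc in analyzable
    ]
    table = classification_table(analyzable, results,
                                 config.pct_cutoff_ng_ml)
    cross = diagnosis_cross_table(results)
    if analyzable:
        t_any, rep_any, t_acc, rep_acc = pct_accuracy(
            analyzable, results, config.pct_cutoff_ng_ml,
            config.ci_level, config.ci_method,
        )
    else:
        logger.warning("no analyzable encounters after filtering")
        t_any = rep_any = t_acc = rep_acc = None
    report = PipelineReport(
        config=config,
        n_screened=len(cohort),
        n_sterile=sterile,
        n_contaminated=contaminated,
        classification=table,
        cross_table=cross,
        dta_any=rep_any,
        dta_accordant=rep_acc,
        two_by_two_any=t_any,
        two_by_two_accordant=t_acc,
        bc_avoidance=simulate_bc_avoidance(analyzable,
                                           config.pct_cutoff_ng_ml),
        abs_possible=simulate_abs_impact(results, TreatmentThreshold.POSSIBLE),
        abs_probable=simulate_abs_impact(results, TreatmentThreshold.PROBABLE),
        constraint_report=(
            check_constraints(cohort, default_constraints(),
                              config.pct_cutoff_ng_ml)
            if config.source == "fixture" else None
        ),
    )
    if config.output_dir:
        _write_outputs(report, cohort)
    return report


def summary_markdown(rep: PipelineReport) -> str:
    """Human-readable run summary."""
    lines = [
        "# 3F pipeline run",
        "",
        f"- screened encounters: {rep.n_screened}",
        f"- excluded: {rep.n_sterile} sterile, "
        f"{rep.n_contaminated} contaminated urine cultures",
        f"- analyzable encounters: {rep.n_analyzed}",
        "",
        "## Diagnosis distribution",
        "",
        rep.cross_table.to_markdown(index=False),
        "",
        "## Blood-culture avoidance",
        "",
        f"- no blood cultures recommended (3F score 0 and/or PCT < "
        f"{rep.config.pct_cutoff_ng_ml} ng/mL): "
        f"{rep.bc_avoidance.n_bc_avoided}/{rep.bc_avoidance.n_total} "
        f"({100 * rep.bc_avoidance.bc_avoided_fraction:.1f}%)",
        "",
        "## Stewardship impact",
        "",
    ]
    for abs_rep in (rep.abs_possible, rep.abs_probable):
        lines.append(
            f"- threshold `{abs_rep.threshold.value}`: withhold "
            f"{abs_rep.n_withheld}, narrow {abs_rep.n_narrowed} "
            f"({abs_rep.n_eligible}/{abs_rep.n_total}, "
            f"{100 * abs_rep.eligible_fraction:.1f}%)"
        )
    if rep.n_analyzed == 0:
        lines += ["", "**no analyzable encounters**"]
    if rep.constraint_report is not None:
        ok = rep.constraint_report.ok
        lines += [
            "",
            "## Constraint check",
            "",
            f"- hard constraints satisfied: {'yes' if ok else 'NO'}",
        ]
        for chk in rep.constraint_report.hard_violations:
            lines.append(
                f"- VIOLATED {chk.name}: expected {chk.expected}, "
                f"observed {chk.observed}"
            )
    return "\n".join(lines) + "\n"


def _write_outputs(rep: PipelineReport, cohort: Sequence[Encounter]) -> None:
    out = Path(rep.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rep.classification.to_csv(out / "classification.csv", index=False)
    rep.cross_table.to_csv(out / "cross_table.csv", index=False)
    if rep.dta_any is not None:
        pd.concat([
            _dta_frame("any_true_bacteraemia", rep.two_by_two_any,
                       rep.dta_any),
            _dta_frame("accordant_bacteraemia", rep.two_by_two_accordant,
                       rep.dta_accordant),
        ]).to_csv(out / "pct_accuracy.csv", index=False)
    steward = pd.DataFrame([
        {
            "threshold": r.threshold.value,
            "n_withheld": r.n_withheld,
            "n_narrowed": r.n_narrowed,
            "n_eligible": r.n_eligible,
            "eligible_fraction": r.eligible_fraction,
        }
        for r in (rep.abs_possible, rep.abs_probable)
    ])
    steward.to_csv(out / "stewardship.csv", index=False)
    if rep.constraint_report is not None:
        pd.DataFrame([
            {
                "constraint": c.name, "expected": c.expected,
                "observed": c.observed, "hard": c.hard,
                "satisfied": c.satisfied,
            }
            for c in rep.constraint_report.checks
        ]).to_csv(out / "constraint_check.csv", index=False)
    write_cohort(cohort, out / "cohort.csv")
    (out / "summary.md").write_text(summary_markdown(rep))
    manifest = {
        "triplef_version": __version__,
        "python": platform.python_version(),
        "config": dataclasses.asdict(rep.config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
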