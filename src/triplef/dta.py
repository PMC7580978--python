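"""Diagnostic-test-accuracy statistics.

2x2 construction, sensitivity / specificity / PPV / NPV with exact
(Clopper–Pearson) 95% confidence intervals, Youden's index J = Se + Sp - 1
with an exhaustive-threshold cutoff search, and Cohen's kappa with an
asymptotic standard-error interval.

Binomial metrics are simple proportions, so their intervals come from
``statsmodels``' exact binomial method; a metric with a zero denominator is
reported as undefined rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class TwoByTwo:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name}={v} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    value: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class DTAReport:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    youden_j: float | None
    kappa: MetricEstimate | None = None


def build_two_by_two(
    test_positive: Sequence[bool], condition_positive: Sequence[bool]
) -> TwoByTwo:
    """Cross paired indicator sequences into a 2x2 table."""
    if len(test_positive) != len(condition_positive):
        raise ValueError(
            f"length mismatch: {len(test_positive)} test indicators vs "
            f"{len(condition_positive)} condition indicators"
        )
    t = np.asarray(test_positive, dtype=bool)
    c = np.asarray(condition_positive, dtype=bool)
    return TwoByTwo(
        tp=int(np.sum(t & c)),
        fp=int(np.sum(t & ~c)),
        fn=int(np.sum(~t & c)),
        tn=int(np.sum(~t & ~c)),
    )


def _proportion(k: int, n: int, ci_level: float, method: str) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(None, None, None)
    lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method=method)
    return MetricEstimate(k / n, float(lo), float(hi))


def dta_metrics(
    t: TwoByTwo, ci_level: float = 0.95, ci_method: str = "beta"
) -> DTAReport:
    """Sensitivity, specificity, PPV, NPV and Youden's J with CIs.

    ``ci_method`` follows statsmodels' ``proportion_confint``: ``"beta"``
    is the exact Clopper–Pearson interval (default), ``"wilson"`` the
    score interval.
    """
    if t.total <= 0:
        raise ValueError("empty 2x2 table")
    sens = _proportion(t.tp, t.tp + t.fn, ci_level, ci_method)
    spec = _proportion(t.tn, t.tn + t.fp, ci_level, ci_method)
    ppv = _proportion(t.tp, t.tp + t.fp, ci_level, ci_method)
    npv = _proportion(t.tn, t.tn + t.fn, ci_level, ci_method)
    j = (
        sens.value + spec.value - 1
        if sens.defined and spec.defined
        else None
    )
    return DTAReport(sens, spec, ppv, npv, j)


def youden_index(t: TwoByTwo) -> float:
    """J = sensitivity + specificity - 1."""
    r = dta_metrics(t)
    if r.youden_j is None:
        raise ValueError("Youden's index undefined: no positives or no negatives")
    return r.youden_j


def select_youden_cutoff(
    marker_values: Sequence[float], condition: Sequence[bool]
) -> tuple[float, float]:
    """Choose the marker threshold maximizing Youden's J.

    Candidate thresholds are every distinct observed value plus +inf (the
    never-positive rule); the test calls a case positive when
    ``marker >= threshold``.  Ties go to the smallest threshold.  Returns
    ``(cutoff, J)``.
    """
    x = np.asarray(marker_values, dtype=float)
    y = np.asarray(condition, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("marker values and condition labels differ in length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cutoff selection needs both condition classes")
    candidates = np.append(np.unique(x), np.inf)
    best_cut, best_j = None, -np.inf
    for c in candidates:
        pred = x >= c
        j = (
            int((pred & y).sum()) / n_pos
            + int((~pred & ~y).sum()) / n_neg
            - 1.0
        )
        if j > best_j:  # strict: earlier (smaller) candidate wins ties
            best_cut, best_j = float(c), float(j)
    return best_cut, best_j


def cohens_kappa(
    t: TwoByTwo, ci_level: float = 0.95
) -> MetricEstimate:
    """Chance-corrected agreement of the two binary classifications.

    kappa = (Po - Pe) / (1 - Pe) with observed agreement Po and chance
    agreement Pe from the marginal products; the CI uses the asymptotic
    standard error sqrt(Po (1 - Po) / (n (1 - Pe)^2)).  Degenerate margins
    (Pe = 1) leave kappa undefined.
    """
    n = t.total
    if n <= 0:
        raise ValueError("empty 2x2 table")
    po = (t.tp + t.tn) / n
    p_test = (t.tp + t.fp) / n
    p_cond = (t.tp + t.fn) / n
    pe = p_test * p_cond + (1 - p_test) * (1 - p_cond)
    if pe == 1.0:
        return MetricEstimate(None, None, None)
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / n) / (1 - pe)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return MetricEstimate(kappa, kappa - z * se, kappa + z * se)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, as in clinical tables."""
    factor = 10.0 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)
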