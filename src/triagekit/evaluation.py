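"""Triage-system comparison artifacts.

Builds the standard evaluation layer for comparing two or more triage
systems on one cohort:

* category-by-category reclassification tables plus the flow list a
  Sankey diagram is drawn from;
* per-category outcome tables (participants, admissions, deaths, with
  percentages);
* dichotomized 2x2 confusion tables — high acuity (emergency) vs low
  acuity (priority and non-urgent) against a binary outcome — and the
  diagnostic statistics sensitivity, specificity, PPV and NPV with 95%
  Wilson score confidence intervals.

Patients with an unknown hospital outcome are excluded from every
outcome denominator. Percentages destined for reporting are rounded to
one decimal with half-away-from-zero ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import TriageCategory

__all__ = [
    "TransitionTable",
    "DiagnosticSummary",
    "transition_table",
    "category_outcome_table",
    "dichotomize",
    "confusion_2x2",
    "diagnostic_summary",
    "wilson_interval",
    "agreement_proportion",
    "round_half_away",
]

CATEGORY_ORDER = (
    TriageCategory.EMERGENCY,
    TriageCategory.PRIORITY,
    TriageCategory.NON_URGENT,
)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with half-away-from-zero ties (table-reporting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TransitionTable:
    """3x3 reclassification counts between two triage systems."""

    counts: pd.DataFrame  # index: system A category, columns: system B category
    system_a: str
    system_b: str

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def agreement(self) -> float:
        """Fraction of patients classified identically by both systems."""
        return float(np.trace(self.counts.to_numpy()) / self.total)

    def flows(self) -> list[dict]:
        """Sankey flow list: one {source, target, value} per nonzero cell."""
        out = []
        for a in self.counts.index:
            for b in self.counts.columns:
                v = int(self.counts.loc[a, b])
                if v:
                    out.append(
                        {
                            "source": f"{self.system_a}: {a}",
                            "target": f"{self.system_b}: {b}",
                            "value": v,
                        }
                    )
        return out


def transition_table(
    cats_a: Sequence[TriageCategory],
    cats_b: Sequence[TriageCategory],
    *,
    system_a: str = "A",
    system_b: str = "B",
) -> TransitionTable:
    """Cross-tabulate categories under two systems, in acuity order."""
    if len(cats_a) != len(cats_b):
        raise ValueError(
            f"length mismatch: {len(cats_a)} vs {len(cats_b)} categories"
        )
    labels = [c.label for c in CATEGORY_ORDER]
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for a, b in zip(cats_a, cats_b):
        counts.loc[a.label, b.label] += 1
    counts.index.name = system_a
    counts.columns.name = system_b
    return TransitionTable(counts=counts, system_a=system_a, system_b=system_b)


def agreement_proportion(
    cats_a: Sequence[TriageCategory], cats_b: Sequence[TriageCategory]
) -> float:
    """Fraction of positions with identical category under both systems."""
    if len(cats_a) != len(cats_b):
        raise ValueError("length mismatch")
    if not cats_a:
        raise ValueError("empty input")
    return sum(a == b for a, b in zip(cats_a, cats_b)) / len(cats_a)


def category_outcome_table(
    cats: Sequence[TriageCategory],
    admitted: Sequence[bool],
    died: Sequence[bool],
    outcome_known: Optional[Sequence[bool]] = None,
) -> pd.DataFrame:
    """Per-category participant, admission and death counts with percentages.

    Participant percentages are of the outcome-known total; admission and
    death percentages are within-category. Unknown-outcome patients are
    excluded from every count and denominator.
    """
    n = len(cats)
    if not (len(admitted) == len(died) == n) or (
        outcome_known is not None and len(outcome_known) != n
    ):
        raise ValueError("length mismatch among input vectors")
    known = (
        np.ones(n, dtype=bool)
        if outcome_known is None
        else np.asarray(outcome_known, dtype=bool)
    )
    adm = np.asarray(admitted, dtype=bool)
    dd = np.asarray(died, dtype=bool)
    cat_arr = np.array([int(c) for c in cats])

    total_known = int(known.sum())
    rows = []
    for cat in CATEGORY_ORDER:
        mask = (cat_arr == int(cat)) & known
        n_cat = int(mask.sum())
        n_adm = int((mask & adm).sum())
        n_died = int((mask & dd).sum())
        rows.append(
            {
                "category": cat.label,
                "participants": n_cat,
                "participants_pct": (
                    round_half_away(100 * n_cat / total_known) if total_known else 0.0
                ),
                "admitted": n_adm,
                "admitted_pct": round_half_away(100 * n_adm / n_cat) if n_cat else 0.0,
                "died": n_died,
                "died_pct": round_half_away(100 * n_died / n_cat) if n_cat else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def dichotomize(cat: TriageCategory) -> str:
    """Collapse the three acuity levels to {high, low}: emergency is high;
    priority and non-urgent are low."""
    return "high" if cat == TriageCategory.EMERGENCY else "low"


def confusion_2x2(
    cats: Sequence[TriageCategory],
    outcome: Sequence[bool],
    outcome_known: Optional[Sequence[bool]] = None,
) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) for high-acuity classification against an outcome.

    Restricted to outcome-known patients: tp = high acuity with the
    outcome, fp = high acuity without, fn = low acuity with, tn = low
    acuity without.
    """
    n = len(cats)
    if len(outcome) != n or (outcome_known is not None and len(outcome_known) != n):
        raise ValueError("length mismatch among input vectors")
    known = (
        np.ones(n, dtype=bool)
        if outcome_known is None
        else np.asarray(outcome_known, dtype=bool)
    )
    y = np.asarray(outcome, dtype=bool)
    high = np.array([dichotomize(c) == "high" for c in cats])
    tp = int((high & y & known).sum())
    fp = int((high & ~y & known).sum())
    fn = int((~high & y & known).sum())
    tn = int((~high & ~y & known).sum())
    return tp, fp, fn, tn


def wilson_interval(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion.

    Continuity-uncorrected; always contains x/n and lies within [0, 1].
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    if not 0 < conf < 1:
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    z = float(norm.ppf(0.5 + conf / 2))
    phat = x / n
    denom = 1 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    lo = 0.0 if x == 0 else max(0.0, centre - half)  # exact at the boundaries
    hi = 1.0 if x == n else min(1.0, centre + half)
    return lo, hi


@dataclass(frozen=True)
class DiagnosticSummary:
    """Diagnostic statistics from a 2x2 table, with 95% Wilson CIs.

    Any statistic with a zero denominator is NaN along with its interval.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]

    def to_frame(self, *, percent: bool = True) -> pd.DataFrame:
        """One row per statistic with point estimate and CI bounds."""
        scale = 100.0 if percent else 1.0
        rows = []
        for stat in ("sensitivity", "specificity", "ppv", "npv"):
            est = getattr(self, stat)
            lo, hi = getattr(self, f"{stat}_ci")
            rows.append(
                {
                    "statistic": stat,
                    "estimate": est * scale,
                    "ci_low": lo * scale,
                    "ci_high": hi * scale,
                }
            )
        return pd.DataFrame(rows).set_index("statistic")


def _stat_with_ci(x: int, n: int, conf: float) -> tuple[float, tuple[float, float]]:
    if n == 0:
        return float("nan"), (float("nan"), float("nan"))
    return x / n, wilson_interval(x, n, conf)


def diagnostic_summary(
    tp: int, fp: int, fn: int, tn: int, *, conf: float = 0.95
) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV and NPV with Wilson CIs from a 2x2."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("cell counts must be nonnegative")
    sens, sens_ci = _stat_with_ci(tp, tp + fn, conf)
    spec, spec_ci = _stat_with_ci(tn, tn + fp, conf)
    ppv, ppv_ci = _stat_with_ci(tp, tp + fp, conf)
    npv, npv_ci = _stat_with_ci(tn, tn + fn, conf)
    return DiagnosticSummary(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        ppv=ppv,
        ppv_ci=ppv_ci,
        npv=npv,
        npv_ci=npv_ci,
    )
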