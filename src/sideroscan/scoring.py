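"""Golde/Doucet hemosiderin scoring.

Each alveolar macrophage is assigned a grade 0-4 by its cytoplasmic
hemosiderin content.  The Doucet total hemosiderin score (THS) over a
300-cell count is sum(n_g * g) / 3, i.e. 100x the mean grade; this module
uses ``round(100 * mean_grade)`` for any cell count N, which reduces to the
Doucet formula at N = 300 and is scale-invariant in the counts.  A THS
strictly above 75 confirms the diagnosis of pulmonary hemorrhage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .annotations import GRADES, GradeCounts

THS_MAX = 400
DIAGNOSIS_THRESHOLD = 75


class UndefinedScoreError(ValueError):
    """Scoring was requested for an empty cell count."""


def _require_cells(counts: GradeCounts) -> None:
    if counts.total == 0:
        raise UndefinedScoreError("score undefined: no cells counted")


def mean_grade(counts: GradeCounts) -> float:
    """Weighted mean grade sum(g * n_g) / N."""
    _require_cells(counts)
    n = counts.as_tuple()
    return sum(g * n[g] for g in GRADES) / counts.total


def grade_sd(counts: GradeCounts) -> float:
    """Population (n-denominator) standard deviation of the grades."""
    _require_cells(counts)
    n = counts.as_tuple()
    m = mean_grade(counts)
    second = sum(g * g * n[g] for g in GRADES) / counts.total
    return math.sqrt(max(second - m * m, 0.0))


def _round_half_away(x: float) -> int:
    # Table scores round halves away from zero (235 from 234.86, 133 from
    # 132.83), unlike banker's rounding.
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def total_hemosiderin_score(counts: GradeCounts) -> int:
    """THS = round(100 * mean grade), range 0..400.

    For a 300-cell differential this equals the Doucet formulation
    sum(n_g * g) / 3 exactly.
    """
    _require_cells(counts)
    return _round_half_away(100.0 * mean_grade(counts))


def diagnose(ths: int) -> bool:
    """Pulmonary hemorrhage is confirmed iff THS > 75 (strict)."""
    if not 0 <= ths <= THS_MAX:
        raise ValueError(f"THS {ths} outside [0, {THS_MAX}]")
    return ths > DIAGNOSIS_THRESHOLD


@dataclass(frozen=True)
class SlideScore:
    """Scoring summary for one slide or region."""

    counts: GradeCounts
    mean_grade: float
    grade_sd: float
    ths: int
    diagnosis_positive: bool

    @classmethod
    def from_counts(cls, counts: GradeCounts) -> "SlideScore":
        m = mean_grade(counts)
        ths = total_hemosiderin_score(counts)
        return cls(counts, m, grade_sd(counts), ths, diagnose(ths))


def dataset_summary(totals: list[int]) -> tuple[int, float, float]:
    """(sum, mean, sample SD) of per-slide cell totals.

    The SD uses the n-1 denominator; for a single slide it is reported as
    0.0 by convention.
    """
    if not totals:
        raise ValueError("empty list of slide totals")
    n = len(totals)
    total = sum(totals)
    mean = total / n
    if n == 1:
        return total, mean, 0.0
    var = sum((t - mean) ** 2 for t in totals) / (n - 1)
    return total, mean, math.sqrt(var)
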