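"""Screening funnel and confusion-matrix partition of the modeled cohort.

The funnel applies the LDCT-positive rate and the 6-29 mm nodule share to
the screened population; the resulting whole-person counts are rounded
half-up. The diagnostic test then splits the cohort into expected TP/FP/
TN/FN cells, which stay fractional: all downstream costing is
expectation-based, so no per-cell rounding is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model_config import DiagnosticTestParams, ScreeningFunnelParams


def round_half_up(x: float) -> int:
    """Round a non-negative value to the nearest integer, halves up."""
    if x < 0:
        raise ValueError("expected a non-negative count")
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    """Expected persons in each test-outcome-by-disease cell (fractional)."""

    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def positives(self) -> float:
        """Expected persons with a positive test result."""
        return self.tp + self.fp

    def as_dict(self) -> dict[str, float]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def screening_funnel(funnel: ScreeningFunnelParams) -> tuple[int, int]:
    """Return (LDCT-positive count, modeled cohort count).

    Both stages round half-up to whole persons: with the base population of
    823 600, a 27.3% positive rate and a 61.63% in-range share this yields
    224 843 positives and a cohort of 138 571.
    """
    n_positive = round_half_up(funnel.n_screened * funnel.p_ldct_positive)
    n_cohort = round_half_up(n_positive * funnel.p_nodule_in_range)
    return n_positive, n_cohort


def confusion_partition(n_cohort: float, test: DiagnosticTestParams) -> ConfusionCounts:
    """Partition the cohort into expected TP/FP/TN/FN cells.

    tp = n * prev * sens, fn = n * prev * (1 - sens),
    fp = n * (1 - prev) * (1 - spec), tn = n * (1 - prev) * spec.
    Cells are left fractional; their sum equals ``n_cohort`` exactly up to
    float rounding.
    """
    if n_cohort < 0:
        raise ValueError("cohort size must be non-negative")
    diseased = n_cohort * test.prevalence
    healthy = n_cohort * (1.0 - test.prevalence)
    return ConfusionCounts(
        tp=diseased * test.sensitivity,
        fn=diseased * (1.0 - test.sensitivity),
        fp=healthy * (1.0 - test.specificity),
        tn=healthy * test.specificity,
    )
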