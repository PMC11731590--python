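"""Per-patient expected diagnostic-assessment costs and payer pricing.

A group's per-patient cost can come from two places:

* **aggregate override** — the printed total average expected assessment
  cost per patient for that payer, used as-is (payer price multipliers are
  NOT applied: each payer carries its own printed value, and the printed
  private costs are not a fixed multiple of the Medicare ones);
* **procedure-level computation** — sum over the five follow-up procedures
  of P(procedure within the year) times its volume-adjusted expected cost,
  where the payer multiplier scales every price.

The volume-adjusted expected cost of a procedure is its per-use cost (base
price plus complication rate times incremental complication cost) scaled by
the group's mean procedure count per patient — the only arrangement of the
four ingredients consistent with their units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .model_config import (
    BIOPSY_PROCEDURES,
    GroupUtilizationProfile,
    PayerPerspective,
    ProcedureCostInput,
)


@dataclass(frozen=True)
class GroupAssessmentCost:
    """Expected diagnostic-assessment cost per patient for one group."""

    group: str
    cost_per_patient: float
    provenance: str  # "computed" | "printed-override"


def unweighted_average_rate(rates: Sequence[float]) -> float:
    """Arithmetic mean of complication rates pooled across sources.

    Each source study contributes equally regardless of its sample size.
    """
    if len(rates) == 0:
        raise ValueError("need at least one rate")
    for r in rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate out of [0,1]: {r}")
    return sum(rates) / len(rates)


def derive_procedure_probabilities(
    profile: GroupUtilizationProfile,
) -> dict[str, float]:
    """Yearly probability of each of the five procedures for one group.

    Biopsy-type probabilities are the product of the overall yearly biopsy
    probability and the conditional biopsy-type share; chest imaging and
    PET/CT probabilities pass through from the profile directly.
    """
    probs: dict[str, float] = dict(profile.p_procedure)
    for proc in BIOPSY_PROCEDURES:
        probs[proc] = profile.p_biopsy_year * profile.p_biopsy_type[proc]
    return probs


def volume_adjusted_cost(
    proc: ProcedureCostInput, mean_count: float, multiplier: float = 1.0
) -> float:
    """Expected cost of using a procedure, scaled by uses per patient.

    (base price + AE rate x AE incremental cost) x payer multiplier x mean
    procedure count.
    """
    per_use = proc.base_price + proc.ae_rate * proc.ae_incremental_cost
    return per_use * multiplier * mean_count


def group_assessment_cost(
    profile: GroupUtilizationProfile,
    procedures: Optional[Iterable[ProcedureCostInput]] = None,
    multiplier: float = 1.0,
    payer: Optional[str] = None,
) -> GroupAssessmentCost:
    """Total average expected diagnostic-assessment cost per patient.

    If the profile carries an aggregate override for ``payer``, that printed
    value is returned unchanged by the multiplier; otherwise the cost is the
    probability-weighted sum of volume-adjusted procedure costs at the
    payer's price level. ``profile.cost_scale`` multiplies either route.
    """
    override = profile.expected_assessment_cost
    if override is not None:
        if payer is None:
            raise ValueError("payer name required to select the aggregate override")
        if payer not in override:
            raise ValueError(
                f"no aggregate assessment cost for payer {payer!r} in group "
                f"{profile.group!r} (have {sorted(override)})"
            )
        return GroupAssessmentCost(
            group=profile.group,
            cost_per_patient=override[payer] * profile.cost_scale,
            provenance="printed-override",
        )
    if procedures is None:
        raise ValueError(
            f"group {profile.group!r} has neither an aggregate assessment cost "
            "nor a procedure cost table"
        )
    probs = derive_procedure_probabilities(profile)
    total = 0.0
    for proc in procedures:
        p = probs.get(proc.name, 0.0)
        total += p * volume_adjusted_cost(proc, profile.mean_procedure_count, multiplier)
    return GroupAssessmentCost(
        group=profile.group,
        cost_per_patient=total * profile.cost_scale,
        provenance="computed",
    )


def weighted_followup_cost(c_spn: float, c_lcdx: float, w: float) -> float:
    """Blend SPN- and LCDx-level per-patient costs by the LCDx share ``w``.

    ``w`` is the share of the cohort with nodules >= 10 mm, whose follow-up
    is costed at the confirmed-diagnosis level.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight out of [0,1]: {w}")
    return (1.0 - w) * c_spn + w * c_lcdx


def assessment_costs_for_perspective(
    spn: GroupUtilizationProfile,
    lcdx: GroupUtilizationProfile,
    perspective: PayerPerspective,
    procedures: Optional[Sequence[ProcedureCostInput]] = None,
) -> Mapping[str, GroupAssessmentCost]:
    """Per-patient assessment costs for both groups under one payer."""
    return {
        g.group: group_assessment_cost(
            g,
            procedures=procedures,
            multiplier=perspective.price_multiplier,
            payer=perspective.name,
        )
        for g in (spn, lcdx)
    }
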