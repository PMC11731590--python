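"""Arm totals and cost savings for each payer perspective and scenario.

Two diagnostic pathways are compared over a 1-year horizon:

* **LDCT-only (standard of care)** — every cohort member is assumed to
  proceed to diagnostic follow-up costed at the confirmed-diagnosis (LCDx)
  per-patient level.
* **Sputum-test arm** — every cohort member pays the test price; the
  expected TP and FP persons additionally pay the weighted SPN/LCDx
  follow-up cost; TN pay the test only. In the false-negative scenario the
  expected FN persons also pay the weighted follow-up cost, since their
  nodules are expected to grow and require attention within the year.

Savings are the LDCT-only total minus the test-arm total. All accounting
uses fractional expected persons; nothing is rounded inside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort_flow import ConfusionCounts, confusion_partition, screening_funnel
from .cost_engine import assessment_costs_for_perspective, weighted_followup_cost
from .model_config import ModelParams

SCENARIOS = ("base", "with_fn_followup")


@dataclass(frozen=True)
class ArmResult:
    """Total expected 1-year cost of one diagnostic arm under one payer."""

    arm: str  # "cypath" | "ldct_only"
    perspective: str
    cell_costs: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.cell_costs.values())


@dataclass(frozen=True)
class SavingsResult:
    perspective: str
    scenario: str  # "base" | "with_fn_followup"
    savings_cohort: float
    savings_per_patient: float


@dataclass(frozen=True)
class PerspectiveRun:
    """All intermediate and final quantities for one payer perspective."""

    perspective: str
    test_price_effective: float
    cost_spn: float
    cost_lcdx: float
    cost_weighted: float
    ldct_arm: ArmResult
    cypath_arm_base: ArmResult
    cypath_arm_fn: ArmResult
    savings: dict[str, SavingsResult]


@dataclass(frozen=True)
class RunResult:
    """Full model output: funnel, confusion cells, and per-payer results."""

    n_ldct_positive: int
    n_cohort: int
    counts: ConfusionCounts
    perspectives: dict[str, PerspectiveRun] = field(default_factory=dict)

    def savings(self, perspective: str, scenario: str = "base") -> SavingsResult:
        return self.perspectives[perspective].savings[scenario]


def cypath_arm_cost(
    counts: ConfusionCounts,
    test_price_effective: float,
    c_weighted: float,
    include_fn_followup: bool = False,
    perspective: str = "",
) -> ArmResult:
    """Expected cost of the sputum-test arm, split by confusion cell.

    Every expected person pays the effective test price; TP and FP (and FN
    when ``include_fn_followup``) additionally pay the weighted follow-up
    cost. TN never pay follow-up.
    """
    fn_followup = c_weighted if include_fn_followup else 0.0
    cells = {
        "tp": counts.tp * (test_price_effective + c_weighted),
        "fp": counts.fp * (test_price_effective + c_weighted),
        "tn": counts.tn * test_price_effective,
        "fn": counts.fn * (test_price_effective + fn_followup),
    }
    return ArmResult(arm="cypath", perspective=perspective, cell_costs=cells)


def ldct_arm_cost(
    n_cohort: float, c_lcdx: float, perspective: str = ""
) -> ArmResult:
    """Expected cost of the LDCT-only arm: every cohort member follows up
    at the LCDx per-patient cost."""
    return ArmResult(
        arm="ldct_only",
        perspective=perspective,
        cell_costs={"positives": n_cohort * c_lcdx},
    )


def compute_savings(
    ldct: ArmResult, cypath: ArmResult, n_cohort: float, scenario: str = "base"
) -> SavingsResult:
    """Savings = LDCT-only total minus test-arm total, per cohort and per patient."""
    if ldct.perspective != cypath.perspective:
        raise ValueError(
            f"perspective mismatch: {ldct.perspective!r} vs {cypath.perspective!r}"
        )
    if n_cohort == 0:
        raise ZeroDivisionError("per-patient savings undefined for an empty cohort")
    savings = ldct.total - cypath.total
    return SavingsResult(
        perspective=ldct.perspective,
        scenario=scenario,
        savings_cohort=savings,
        savings_per_patient=savings / n_cohort,
    )


def run_model(params: ModelParams) -> RunResult:
    """Run the full pipeline: funnel -> partition -> costing -> arms -> savings.

    Deterministic: identical parameters give bit-identical results.
    """
    n_positive, n_cohort = screening_funnel(params.funnel)
    counts = confusion_partition(n_cohort, params.test)

    per_persp: dict[str, PerspectiveRun] = {}
    for persp in params.perspectives:
        costs = assessment_costs_for_perspective(
            params.spn, params.lcdx, persp, procedures=params.procedures
        )
        c_spn = costs["SPN"].cost_per_patient
        c_lcdx = costs["LCDx"].cost_per_patient
        c_weighted = weighted_followup_cost(c_spn, c_lcdx, params.lcdx_weight)
        test_eff = persp.test_price * persp.price_multiplier

        ldct = ldct_arm_cost(n_cohort, c_lcdx, perspective=persp.name)
        cy_base = cypath_arm_cost(
            counts, test_eff, c_weighted, include_fn_followup=False,
            perspective=persp.name,
        )
        cy_fn = cypath_arm_cost(
            counts, test_eff, c_weighted, include_fn_followup=True,
            perspective=persp.name,
        )
        savings = {
            "base": compute_savings(ldct, cy_base, n_cohort, scenario="base"),
            "with_fn_followup": compute_savings(
                ldct, cy_fn, n_cohort, scenario="with_fn_followup"
            ),
        }
        per_persp[persp.name] = PerspectiveRun(
            perspective=persp.name,
            test_price_effective=test_eff,
            cost_spn=c_spn,
            cost_lcdx=c_lcdx,
            cost_weighted=c_weighted,
            ldct_arm=ldct,
            cypath_arm_base=cy_base,
            cypath_arm_fn=cy_fn,
            savings=savings,
        )

    return RunResult(
        n_ldct_positive=n_positive,
        n_cohort=n_cohort,
        counts=counts,
        perspectives=per_persp,
    )
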