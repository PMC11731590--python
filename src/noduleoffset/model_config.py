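"""Parameter schema for the cost-offset model.

Every model symbol lives here as a validated pydantic type. Conventions,
chosen once to prevent silent 100x errors:

* probabilities are stored as fractions in [0, 1], never percent;
* money is US dollars (float64 keeps cents exactly at cohort totals of
  order 1e9; rounding happens only at the display boundary);
* payer-dependent printed per-patient costs are stored per payer.

Configuration files are YAML (JSON is a subset and also accepted).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Canonical labels for the five follow-up procedures in the care pathway.
PROCEDURES = (
    "chest imaging",
    "PET/CT",
    "CT-guided biopsy",
    "bronchoscopy",
    "surgical biopsy",
)

#: The three procedures that are biopsies (their yearly probabilities are
#: derived as p_biopsy_year * p_biopsy_type, not read from the config).
BIOPSY_PROCEDURES = ("CT-guided biopsy", "bronchoscopy", "surgical biopsy")

GROUP_LABELS = ("SPN", "LCDx")
PAYER_LABELS = ("medicare", "private")

#: Tolerance for a set of printed, rounded probabilities summing to one
#: (e.g. biopsy-type shares printed to two decimals of a percent).
PRINTED_SUM_TOL = 5e-3


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ScreeningFunnelParams(_Model):
    """Screening funnel: screened population -> LDCT-positive -> nodule 6-29 mm."""

    n_screened: int = Field(ge=0, description="persons screened with LDCT")
    p_ldct_positive: float = Field(ge=0.0, le=1.0)
    p_nodule_in_range: float = Field(
        ge=0.0, le=1.0, description="P(nodule 6-29 mm | LDCT positive)"
    )


class DiagnosticTestParams(_Model):
    """Accuracy of the sputum test and cancer prevalence in the cohort."""

    prevalence: float = Field(ge=0.0, le=1.0)
    sensitivity: float = Field(ge=0.0, le=1.0)
    specificity: float = Field(ge=0.0, le=1.0)


class ProcedureCostInput(_Model):
    """Per-procedure pricing: base price plus expected complication cost.

    ``ae_rate`` is the unweighted average complication rate across the
    published sources for that procedure; ``ae_incremental_cost`` the
    unweighted average incremental cost of a complication.
    """

    name: str
    base_price: float = Field(ge=0.0, description="USD per use, Medicare level")
    ae_rate: float = Field(ge=0.0, le=1.0)
    ae_incremental_cost: float = Field(ge=0.0, description="USD per adverse event")

    @model_validator(mode="after")
    def _known_name(self) -> "ProcedureCostInput":
        if self.name not in PROCEDURES:
            raise ValueError(
                f"unknown procedure {self.name!r}; expected one of {PROCEDURES}"
            )
        return self


class GroupUtilizationProfile(_Model):
    """Follow-up utilization for one patient stratum (SPN or LCDx).

    ``expected_assessment_cost`` maps payer name to the per-patient expected
    diagnostic-assessment cost when that aggregate is supplied directly
    (each payer carries its own printed value); when absent the cost is
    computed from the procedure table. ``cost_scale`` is a dimensionless
    multiplier on the group's final per-patient cost (default 1), the handle
    the sensitivity analysis perturbs.
    """

    group: str
    p_biopsy_year: float = Field(ge=0.0, le=1.0)
    mean_procedure_count: float = Field(ge=0.0)
    p_biopsy_type: dict[str, float] = Field(
        description="biopsy-type shares, conditional on biopsy; keys = 3 biopsy types"
    )
    p_procedure: dict[str, float] = Field(
        default_factory=dict,
        description="direct yearly probabilities (chest imaging, PET/CT)",
    )
    expected_assessment_cost: Optional[dict[str, float]] = Field(
        default=None, description="payer -> USD per patient, direct override"
    )
    cost_scale: float = Field(default=1.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "GroupUtilizationProfile":
        if self.group not in GROUP_LABELS:
            raise ValueError(f"group must be one of {GROUP_LABELS}, got {self.group!r}")
        for d in (self.p_biopsy_type, self.p_procedure):
            for k, v in d.items():
                if k not in PROCEDURES:
                    raise ValueError(f"unknown procedure {k!r}")
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"probability for {k!r} out of [0,1]: {v}")
        missing = set(BIOPSY_PROCEDURES) - set(self.p_biopsy_type)
        if missing:
            raise ValueError(f"p_biopsy_type missing biopsy types: {sorted(missing)}")
        s = sum(self.p_biopsy_type.values())
        if abs(s - 1.0) > PRINTED_SUM_TOL:
            raise ValueError(f"p_biopsy_type values sum to {s:.4f}, expected ~1")
        if self.expected_assessment_cost is not None:
            for payer, c in self.expected_assessment_cost.items():
                if c < 0:
                    raise ValueError(f"negative assessment cost for {payer!r}: {c}")
        return self


class PayerPerspective(_Model):
    """A payer whose price level scales procedure and test prices.

    ``test_price`` is the pre-multiplier (Medicare fee-schedule) price of the
    diagnostic test; the effective price is ``test_price * price_multiplier``.
    """

    name: str
    price_multiplier: float = Field(gt=0.0)
    test_price: float = Field(ge=0.0, description="USD, before multiplier")


class ModelParams(_Model):
    """Complete parameter set for one model run."""

    funnel: ScreeningFunnelParams
    test: DiagnosticTestParams
    groups: list[GroupUtilizationProfile] = Field(min_length=2, max_length=2)
    procedures: Optional[list[ProcedureCostInput]] = None
    lcdx_weight: float = Field(
        ge=0.0, le=1.0,
        description="share of TP/FP follow-up cost allocated to the LCDx level",
    )
    perspectives: list[PayerPerspective] = Field(min_length=1)

    @model_validator(mode="after")
    def _check(self) -> "ModelParams":
        labels = sorted(g.group for g in self.groups)
        if labels != sorted(GROUP_LABELS):
            raise ValueError(f"groups must be exactly one SPN and one LCDx, got {labels}")
        names = [p.name for p in self.perspectives]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate perspective names: {names}")
        if self.procedures is not None:
            pnames = [p.name for p in self.procedures]
            if len(set(pnames)) != len(pnames):
                raise ValueError(f"duplicate procedure names: {pnames}")
        return self

    def group_profile(self, label: str) -> GroupUtilizationProfile:
        for g in self.groups:
            if g.group == label:
                return g
        raise KeyError(label)

    @property
    def spn(self) -> GroupUtilizationProfile:
        return self.group_profile("SPN")

    @property
    def lcdx(self) -> GroupUtilizationProfile:
        return self.group_profile("LCDx")

    def perspective(self, name: str) -> PayerPerspective:
        for p in self.perspectives:
            if p.name == name:
                return p
        raise KeyError(name)


def load_params(path: str | Path) -> ModelParams:
    """Read and validate a parameter file (YAML or JSON).

    Raises ``FileNotFoundError`` for a missing file and
    ``pydantic.ValidationError`` naming the offending field for schema or
    range violations.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return ModelParams.model_validate(raw)


def write_params(params: ModelParams, path: str | Path) -> None:
    """Write ``params`` so that :func:`load_params` round-trips to equality.

    Optional fields that are unset are omitted from the file.
    """
    data = params.model_dump(exclude_none=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)
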