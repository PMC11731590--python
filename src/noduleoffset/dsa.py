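"""One-way deterministic sensitivity analysis with tornado ordering.

Each named parameter is set to a low and a high value (default: base
+/- 20%) with everything else held at base, the model is re-run, and the
swing of the chosen savings outcome is recorded. Bars are ranked by swing
to form a tornado diagram.

Parameters are addressed by dotted paths into the parameter set, e.g.
``test.sensitivity``, ``lcdx_weight``, ``perspectives.private.test_price``,
``groups.lcdx.cost_scale`` or ``procedures.ct_guided_biopsy.ae_rate``.
A path segment applied to a list selects the element whose ``name`` or
``group`` matches (case-insensitive, punctuation-insensitive).

Note that with the aggregate printed per-patient costs in force the
procedure-level complication rates do not enter the calculation at all:
their bars have zero range and are flagged ``inactive under aggregate
costing``. Supply a procedure cost table to activate them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from pydantic import BaseModel, ValidationError

from .arms_savings import run_model
from .model_config import ModelParams

DEFAULT_RELATIVE_SHIFT = 0.20


def _norm(label: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", label.lower()).strip("_")


@dataclass(frozen=True)
class DsaSpec:
    """One parameter to vary, with its low and high values."""

    parameter_path: str
    low_value: float
    high_value: float
    label: Optional[str] = None  # display name for reports

    def __post_init__(self) -> None:
        if self.low_value > self.high_value:
            raise ValueError(
                f"{self.parameter_path}: low {self.low_value} > high {self.high_value}"
            )


@dataclass(frozen=True)
class DsaResult:
    parameter_path: str
    label: str
    low_value: float
    high_value: float
    outcome_low: float
    outcome_high: float
    base_outcome: float
    note: str = ""

    @property
    def range(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _resolve_parent(params: ModelParams, path: str):
    """Walk a dotted path, returning (parent object, final attribute name)."""
    parts = path.split(".")
    obj: object = params
    for i, part in enumerate(parts):
        last = i == len(parts) - 1
        if isinstance(obj, list):
            matches = [
                el for el in obj
                if _norm(getattr(el, "name", getattr(el, "group", ""))) == _norm(part)
            ]
            if not matches:
                raise KeyError(f"cannot resolve {path!r}: no element named {part!r}")
            obj = matches[0]
            # the matched element consumes the segment; re-handle it as attr? no:
            # list selection uses the segment itself, continue with next segment
            continue
        if isinstance(obj, BaseModel):
            if not hasattr(obj, part):
                raise KeyError(f"cannot resolve {path!r}: no field {part!r}")
            if last:
                return obj, part
            obj = getattr(obj, part)
            if obj is None:
                raise KeyError(f"cannot resolve {path!r}: {part!r} is unset")
        else:
            raise KeyError(f"cannot resolve {path!r} at segment {part!r}")
    raise KeyError(f"path {path!r} does not end on a settable field")


def _set_path(params: ModelParams, path: str, value: float) -> str:
    """Set ``value`` at ``path`` in-place, clamping probabilities to [0, 1].

    Returns a note string ("" or a clamping message).
    """
    parent, attr = _resolve_parent(params, path)
    try:
        setattr(parent, attr, value)
        return ""
    except ValidationError:
        clamped = min(1.0, max(0.0, value))
        setattr(parent, attr, clamped)
        return f"value {value:g} clamped to {clamped:g}"


def _outcome(params: ModelParams, perspective: str, scenario: str) -> float:
    return run_model(params).savings(perspective, scenario).savings_cohort


def one_way_dsa(
    params: ModelParams,
    specs: Sequence[DsaSpec],
    perspective: str = "private",
    scenario: str = "base",
) -> list[DsaResult]:
    """Run the one-way analysis; outcome is per-cohort savings.

    The base parameter set is never mutated: every perturbation acts on a
    deep copy. Results come back in input order (use :func:`tornado_rank`
    to sort).
    """
    base_outcome = _outcome(params, perspective, scenario)
    results: list[DsaResult] = []
    for spec in specs:
        if spec.parameter_path.startswith("procedures.") and params.procedures is None:
            # AE rates cannot enter the model when only aggregate printed
            # per-patient costs are supplied; report an honest zero bar.
            results.append(DsaResult(
                parameter_path=spec.parameter_path,
                label=spec.label or spec.parameter_path,
                low_value=spec.low_value,
                high_value=spec.high_value,
                outcome_low=base_outcome,
                outcome_high=base_outcome,
                base_outcome=base_outcome,
                note="inactive under aggregate costing",
            ))
            continue
        notes: list[str] = []
        endpoints: list[float] = []
        for value in (spec.low_value, spec.high_value):
            perturbed = params.model_copy(deep=True)
            note = _set_path(perturbed, spec.parameter_path, value)
            if note:
                notes.append(note)
            endpoints.append(_outcome(perturbed, perspective, scenario))
        res = DsaResult(
            parameter_path=spec.parameter_path,
            label=spec.label or spec.parameter_path,
            low_value=spec.low_value,
            high_value=spec.high_value,
            outcome_low=endpoints[0],
            outcome_high=endpoints[1],
            base_outcome=base_outcome,
            note="; ".join(notes),
        )
        if res.range == 0.0 and _is_inactive_ae_rate(params, spec):
            res = replace(res, note=(res.note + "; " if res.note else "")
                          + "inactive under aggregate costing")
        results.append(res)
    return results


def _is_inactive_ae_rate(params: ModelParams, spec: DsaSpec) -> bool:
    if ".ae_rate" not in spec.parameter_path:
        return False
    return all(g.expected_assessment_cost is not None for g in params.groups)


def tornado_rank(results: Sequence[DsaResult]) -> list[DsaResult]:
    """Sort bars by swing, widest first; ties keep input order (stable sort)."""
    if len(results) == 0:
        raise ValueError("no sensitivity results to rank")
    return sorted(results, key=lambda r: -r.range)


def default_dsa_specs(
    params: ModelParams,
    perspective: str = "private",
    shift: float = DEFAULT_RELATIVE_SHIFT,
) -> list[DsaSpec]:
    """The seven default tornado parameters.

    LCDx follow-up cost, the test price, the three biopsy complication
    rates, the large-nodule (LCDx weighting) share, and the test's
    sensitivity; each varied by ``shift`` (default 20%) around base, with
    probabilities clamped to [0, 1].
    """
    def around(base: float, clamp: bool = False) -> tuple[float, float]:
        lo, hi = base * (1.0 - shift), base * (1.0 + shift)
        if clamp:
            lo, hi = max(0.0, lo), min(1.0, hi)
        return lo, hi

    specs = [
        DsaSpec("groups.lcdx.cost_scale", *around(params.lcdx.cost_scale),
                label="LCDx follow-up cost"),
        DsaSpec(f"perspectives.{perspective}.test_price",
                *around(params.perspective(perspective).test_price),
                label="test cost"),
    ]
    ae_base = {p.name: p.ae_rate for p in (params.procedures or [])}
    for proc, label in (
        ("CT-guided biopsy", "AE rate, CT-guided biopsy"),
        ("bronchoscopy", "AE rate, bronchoscopy"),
        ("surgical biopsy", "AE rate, surgical biopsy"),
    ):
        base = ae_base.get(proc, 0.0)
        specs.append(
            DsaSpec(f"procedures.{_norm(proc)}.ae_rate", *around(base, clamp=True),
                    label=label)
        )
    specs.append(DsaSpec("lcdx_weight", *around(params.lcdx_weight, clamp=True),
                         label="share of larger nodules (LCDx weight)"))
    specs.append(DsaSpec("test.sensitivity", *around(params.test.sensitivity,
                                                     clamp=True),
                         label="test sensitivity"))
    return specs
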