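"""Independent straight-line recomputation of the whole model.

One flat function, spreadsheet style: reads only parameter fields and
recomputes every output with inline arithmetic, sharing no code with the
package's pipeline. Used to cross-check ``run_model`` on randomized
parameter sets.
"""

import math


def flat_model(params):
    """Return {(perspective, scenario): (savings_cohort, savings_per_patient),
    ('arm_totals', perspective): (ldct_total, cypath_base, cypath_fn)}."""
    f = params.funnel
    n_pos = math.floor(f.n_screened * f.p_ldct_positive + 0.5)
    n = math.floor(n_pos * f.p_nodule_in_range + 0.5)

    t = params.test
    tp = n * t.prevalence * t.sensitivity
    fn = n * t.prevalence * (1.0 - t.sensitivity)
    fp = n * (1.0 - t.prevalence) * (1.0 - t.specificity)
    tn = n * (1.0 - t.prevalence) * t.specificity

    out = {"n_pos": n_pos, "n": n, "cells": (tp, fp, tn, fn)}
    for persp in params.perspectives:
        per_group = {}
        for g in params.groups:
            if g.expected_assessment_cost is not None:
                c = g.expected_assessment_cost[persp.name] * g.cost_scale
            else:
                c = 0.0
                for proc in params.procedures:
                    if proc.name in ("CT-guided biopsy", "bronchoscopy",
                                     "surgical biopsy"):
                        p = g.p_biopsy_year * g.p_biopsy_type[proc.name]
                    else:
                        p = g.p_procedure.get(proc.name, 0.0)
                    per_use = proc.base_price + proc.ae_rate * proc.ae_incremental_cost
                    c += p * per_use * persp.price_multiplier * g.mean_procedure_count
                c *= g.cost_scale
            per_group[g.group] = c
        c_spn, c_lcdx = per_group["SPN"], per_group["LCDx"]
        w = params.lcdx_weight
        cw = (1.0 - w) * c_spn + w * c_lcdx
        teff = persp.test_price * persp.price_multiplier

        cy_base = (tp + fp) * (teff + cw) + (tn + fn) * teff
        cy_fn = cy_base + fn * cw
        ldct = n * c_lcdx
        out[("arm_totals", persp.name)] = (ldct, cy_base, cy_fn)
        out[(persp.name, "base")] = (ldct - cy_base, (ldct - cy_base) / n)
        out[(persp.name, "with_fn_followup")] = (ldct - cy_fn, (ldct - cy_fn) / n)
    return out
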