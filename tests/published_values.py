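"""Published base-case figures the model is checked against.

All money in USD; counts in persons. These are frozen expected values for
tests only — the package never reads them.
"""

FUNNEL = {"n_ldct_positive": 224_843, "n_cohort": 138_571}

# Expected confusion cells implied by dividing each published test-arm cell
# cost by the $760 test price (cells themselves are not printed directly).
CELLS_IMPLIED = {
    "tp": (12_095_106 - 8_139_945) / 760,   # 5 204.2
    "fp": (36_876_610 - 24_817_774) / 760,  # 15 866.9
    "tn": 88_431_467 / 760,                 # 116 357.2
    "fn": 868_206 / 760,                    # 1 142.4
}

MEDICARE = {
    "cypath_cells": {"tp": 12_095_106, "fp": 36_876_610,
                     "tn": 88_431_467, "fn": 868_206},
    "cypath_total": 138_271_389,
    "tp_followup": 8_139_945,
    "fp_followup": 24_817_774,
    "ldct_total": 516_960_408,
    "savings_base": 378_689_020,
    "savings_base_per_patient": 2_733,
    "savings_fn": 376_902_203,
    "savings_fn_per_patient": 2_720,
}

PRIVATE = {
    "cypath_total": 358_677_100,
    "ldct_total": 1_253_879_411,
    "savings_base": 895_202_311,
    "savings_base_per_patient": 6_460,
    "savings_fn": 890_829_889,
    "savings_fn_per_patient": 6_429,
}

ASSESSMENT_COSTS = {
    "medicare": {"SPN": 514.95, "LCDx": 3_730.66},
    "private": {"SPN": 1_299.07, "LCDx": 9_048.67},
}

# Derived per-procedure yearly probabilities as printed (percent/100).
TABLE1_DERIVED_BIOPSY_PROBS = {
    "SPN": {"CT-guided biopsy": 0.0119, "bronchoscopy": 0.0425,
            "surgical biopsy": 0.0071},
    "LCDx": {"CT-guided biopsy": 0.3543, "bronchoscopy": 0.4006,
             "surgical biopsy": 0.0739},
}
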