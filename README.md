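# noduleoffset

A cost-offset model for adding a sputum flow-cytometry lung-cancer
diagnostic (CyPath® Lung) to the care pathway of patients with a positive
low-dose CT (LDCT) screen and an indeterminate pulmonary nodule of
6–29 mm. The package is aimed at health-economics analysts and
reimbursement modellers: it computes, per payer (Medicare and
private/commercial), the expected 1-year cost of the standard-of-care
pathway versus a test-guided pathway, the per-cohort and per-patient
savings, and a one-way deterministic sensitivity analysis (tornado
diagram).

## The model

A screened population `N` passes through a funnel: a fraction
`p_pos = 27.3 %` is LDCT-positive and, of those, `p_range = 61.63 %` carry a
nodule of 6–29 mm, giving the modeled cohort

```
n = round(round(N · p_pos) · p_range)          (half-up, whole persons)
```

With cancer prevalence `π = 4.58 %` and the test's sensitivity
`Se = 0.82` / specificity `Sp = 0.88`, the cohort splits into expected
(fractional) confusion cells

```
TP = n·π·Se      FN = n·π·(1−Se)
FP = n·(1−π)·(1−Sp)   TN = n·(1−π)·Sp
```

Follow-up is costed per patient at one of two utilization levels —
suspicious pulmonary nodule (SPN) or confirmed lung-cancer diagnosis
(LCDx) — either from the published aggregate per-patient costs or from a
procedure-level table (five procedures; cost per use = base price +
complication rate × incremental complication cost, volume-adjusted by the
mean procedure count). Positive-test follow-up uses the blend

```
c_w = (1−w)·c_SPN + w·c_LCDx,   w = share of nodules ≥ 10 mm (33 %)
```

Arm totals: the LDCT-only arm charges every cohort member `c_LCDx`; the
test arm charges everyone the test price (Medicare $760; × 2.64 for private
payers) plus `c_w` for each expected TP and FP — and, in the false-negative
scenario, for each expected FN as well. Savings are the difference between
the arms, per cohort and per patient.

## Worked example

```python
from noduleoffset import paper_base_case, run_model

run = run_model(paper_base_case("calibrated"))
print(f"cohort: {run.n_cohort:,} patients")
for payer in ("medicare", "private"):
    sv = run.savings(payer, "base")
    print(f"{payer:>8}: ${sv.savings_cohort:,.0f} per cohort "
          f"(${sv.savings_per_patient:,.0f}/patient)")
```

prints

```
cohort: 138,571 patients
medicare: $378,687,140 per cohort ($2,733/patient)
 private: $895,199,164 per cohort ($6,460/patient)
```

i.e. adding the test to the pathway is expected to save Medicare about
$379 M on the modeled cohort of 138 571 patients ($2 733 per patient) and a
private payer about $895 M ($6 460 per patient); accounting for
false-negative follow-up trims these slightly (`run.savings(payer,
"with_fn_followup")`). The `"calibrated"` base case uses the LCDx weighting
share 0.3263 implied by the published intermediate totals; `"stated"` uses
the rounder published 33 % (results then shift by well under 1 %).

The same run is available from the shell, along with the sensitivity
analysis and config validation:

```
noduleoffset run --config fixtures/basecase_calibrated.yaml
noduleoffset dsa --variant stated --out dsa.csv
noduleoffset validate --config fixtures/basecase.yaml
```

Parameter files are YAML with probabilities as fractions and money in USD
(see `fixtures/basecase.yaml` for the full schema by example).

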