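# Methods

## Model structure and assumptions

The model is a deterministic, cohort-expectation cost-offset comparison
with a 1-year horizon and no discounting. It is not a microsimulation:
patients are never sampled, and all confusion-matrix cells are expected
(fractional) person counts. Disease progression, QALYs and treatment costs
are out of scope; only diagnostic-assessment costs and procedure
complications are counted. A single screening pass is modeled — no repeat
rounds.

Key structural choices, made where the published account is ambiguous:

* **Funnel rounding.** The two funnel counts are rounded half-up to whole
  persons (823 600 × 0.273 = 224 842.8 → 224 843;
  224 843 × 0.6163 = 138 570.7 → 138 571). Half-up is the only common rule
  consistent with both published counts. Confusion cells are *not*
  rounded: the published arm costs imply fractional expected persons
  (e.g. an FN cell of 868 206 / 760 ≈ 1 142.4).
* **LDCT-only arm.** Every cohort member is charged the LCDx-level
  per-patient cost: 138 571 × $3 730.66 ≈ $516.96 M reproduces the
  published arm total to ~2 × 10⁻⁶; no blended or SPN-level costing does.
* **FN-scenario cost.** The false-negative follow-up cost equals the same
  weighted per-patient cost `c_w` used for TP/FP; this reproduces the
  published base-vs-FN savings deltas on both payer perspectives.
* **Volume-adjusted cost composition.** The published description names
  four ingredients (base price, AE rate, AE incremental cost, mean
  procedure count) but not their arrangement;
  `(price + rate × cost) × count` is the only arrangement whose units work
  (expected cost per use, scaled by expected uses). The mean procedure
  count multiplies every procedure of a group, since one count is reported
  per group, not per procedure.
* **Payer pricing.** The 2.64 private multiplier applies to procedure
  prices and to the test price ($760 → $2 006.40); only with the
  multiplied test price does the private test-arm total reproduce the
  published $358.68 M. It does **not** apply to the aggregate per-patient
  cost overrides: the published private per-patient costs ($1 299.07,
  $9 048.67) are *not* 2.64 × the Medicare ones (ratios ≈ 2.52 and 2.43),
  so each payer carries its own printed override verbatim. The discrepancy
  is documented here rather than silently "fixed".

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| `n_screened` | 823 600 | persons | screened population |
| `p_ldct_positive` | 0.273 | fraction | LDCT-positive rate |
| `p_nodule_in_range` | 0.6163 | fraction | nodule 6–29 mm given positive |
| `prevalence` | 0.0458 | fraction | cancer prevalence in cohort |
| `sensitivity`, `specificity` | 0.82, 0.88 | fraction | test accuracy |
| `p_biopsy_year` | 0.0615 (SPN), 0.8289 (LCDx) | fraction | biopsy within 1 y |
| `mean_procedure_count` | 1.43 (SPN), 1.18 (LCDx) | per patient | volume adjustment |
| `expected_assessment_cost` | 514.95 / 3 730.66 (Medicare), 1 299.07 / 9 048.67 (private) | USD/patient | printed aggregates, used as overrides |
| `lcdx_weight` | 0.33 (stated) or 0.3263 (calibrated) | fraction | share of follow-up at LCDx level |
| `test_price` | 760 | USD | pre-multiplier |
| `price_multiplier` | 1.0 / 2.64 | — | Medicare / private |

All probabilities are stored as fractions (never percent); money is USD in
float64, which keeps sub-cent precision at cohort totals of order 10⁹.
Display rounding to cents happens only in the human-readable CLI tables.

**The calibrated variant.** The stated 33 % LCDx share reproduces the
published results to within 1 % (its two printed digits bound the
attainable agreement). Dividing the published TP follow-up total by the
expected TP count gives a per-patient cost of ≈ $1 564.1, which the blend
matches at `w = 0.3263`; with that weight every published arm total and
savings figure reproduces to better than 0.1 %. Both variants ship as
fixtures (`fixtures/basecase.yaml`, `fixtures/basecase_calibrated.yaml`).

**Complication rates.** The engine always uses the exact unweighted means
of the per-source rates (CT-guided 27.75 %, bronchoscopy 6.57 %, surgical
11.45 %). The published table rounds the CT-guided average to 28.0 % and
prints surgical as 11.5 %/11.47 %; those printed values are kept as
separate reference constants, never silently substituted for exact means.

## Sensitivity analysis

The one-way DSA perturbs seven parameters by ±20 % around base (the LCDx
follow-up cost, the test price, the three biopsy complication rates, the
LCDx weighting share, and test sensitivity), holding everything else fixed,
and ranks the savings swings into a tornado. Probabilities are clamped to
[0, 1] after perturbation and the clamping is reported. The default outcome
is base-scenario per-cohort savings from the private perspective (the
perspective is switchable; the published figure does not say which it
plots, and its bar lengths are not machine-readable, so only the
qualitative ranking — follow-up cost and test price widest — is checked).

The "LCDx follow-up cost" bar is implemented as a multiplicative
`cost_scale` on the group's per-patient cost so that the same dotted
parameter path works under both aggregate-override and procedure-level
costing. Under aggregate costing the complication-rate bars cannot move the
outcome at all; they are reported with zero range and flagged *inactive
under aggregate costing* rather than omitted.

## Synthetic inputs

Two generators make the model fully testable without external data:

* `synthetic_procedure_table()` — per-CPT base prices are not published, so
  this table carries plausible Medicare-magnitude stand-ins sized so the
  computed group costs land near the published aggregates ($528 / $3 485
  per patient vs $514.95 / $3 730.66). Complication incremental costs are
  set at the published minor-complication mean ($6 320), reflecting that
  the tracked complications (pneumothorax, chest-tube placement,
  hemorrhage) are predominantly minor outpatient events. It exists to
  exercise the procedure-level pathway (activating the complication-rate
  tornado bars); it is synthetic and is not used to reproduce published
  totals.
* `random_params(GeneratorSettings(seed))` — structurally valid random
  parameter sets (probabilities in [0, 1], biopsy-type shares summing to 1
  via a Dirichlet draw, non-negative costs, both payers present), used for
  property tests: config round-trip identity, cell conservation, and
  equivalence of the pipeline with an independent straight-line
  "spreadsheet" recomputation. One explicit seeded generator, no global
  random state. These draws emulate the *structure* of valid inputs, not
  the joint distribution of real-world utilization data, so passing
  property tests demonstrates internal consistency, not external validity.

## Numerical notes

* Savings are differences of ~10⁸–10⁹-dollar arm totals; oracle-equivalence
  comparisons therefore use a tolerance of 10⁻⁹ relative to the arm-total
  scale (catastrophic cancellation makes 10⁻⁹ relative to a near-zero
  difference meaningless in float64).
* `tornado_rank` sorts by swing descending with a stable sort, so equal
  bars keep their input order.
* Degenerate inputs: an empty cohort makes per-patient savings undefined
  (an error, not NaN); a zero biopsy probability zeroes all biopsy-type
  probabilities; zero prices propagate to exactly zero costs.

## Limitations

* The model inherits the published inputs' rounding; exact reproduction of
  printed totals is bounded by that rounding (hence the two tolerance
  tiers above).
* Single mean complication cost per procedure — no minor/major severity
  tiers.
* The procedure-level costing route is validated structurally (linearity,
  homogeneity, Table-row reproduction) but its absolute price levels are
  synthetic stand-ins.
* One-year horizon, single payer at a time, no uncertainty propagation
  beyond the one-way DSA (no probabilistic sensitivity analysis).
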