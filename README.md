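# ckdkit

A desk-scale decision core for **early detection and self-monitoring of
chronic kidney disease (CKD)**, aimed at settings where nephrologists are
scarce and screening happens in primary care: community health programs,
mHealth back ends, and methods work on screening-tool agreement studies.

CKD is defined by a reduced glomerular filtration rate (GFR) and by albumin
excretion in urine. `ckdkit` implements the full screening chain plus the
statistical machinery used to evaluate such a tool against human experts:

* **GFR estimation** — Cockcroft-Gault creatinine clearance,
  `C = (140 − I)·K / (72·P)` (× 0.85 for women), with I age in years,
  K weight in kg, P plasmatic creatinine in mg/dL; no race coefficient.
* **Classification** — albuminuria categories at the 30/300 mg/g cut-offs;
  KDIGO stages 1, 2, 3a, 3b, 4, 5 by GFR band; serum biomarker flags
  (creatinine 0.6–1.4 mg/dL, urea 20–40 mg/dL, potassium 3.5–5.5 mEq/L).
* **Risk stratification** — a validated, monotone 18-cell stage × albuminuria
  grid in the KDIGO heat-map style, yielding one of four risk levels
  (low / moderate / high / very high), with referral advice, screening
  reminders and an append-only evaluation history.
* **Comorbidity self-monitoring** — blood-pressure (hypertension) and
  context-specific glucose (diabetes) classification, manual or sensor-fed.
* **Personal health records** — a cohort-table CSV / JSON record model with
  validation and medication/allergy interaction alerts.
* **Clinical documents** — a simplified CDA-style XML template with schema
  validation and lossless round trips, for sharing an evaluation with a
  physician.
* **Agreement statistics** — Cohen's kappa with 95% Wald intervals
  (unclipped), per-category and pooled multi-rater kappas (mean-pairwise or
  Fleiss), the standard interpretation scale, and table-style reports.
* **Synthetic data** — reproducible cohorts with known ground truth and
  rater panels calibrated to a designed kappa, so everything above is
  testable offline.

All clinical cut-offs are configuration (`ckdkit.config`), overridable from
a YAML file. See `docs/methods.md` for the model, its assumptions, and the
design decisions.

## Worked example

Estimate a clearance for a 60-year-old woman, 80 kg, creatinine 0.54 mg/dL:

```console
$ ckdkit gfr --gender F --age 60 --weight 80 --creatinine 0.54
139.9
```

(Full precision 139.917…; displayed values are truncated, not rounded, to
one decimal.)

Evaluate a record — a 79-year-old man, 61 kg, creatinine 0.81 mg/dL,
albumin-to-creatinine ratio 77.5 mg/g:

```console
$ ckdkit evaluate --input row3.csv --timestamp 2016-05-01T00:00:00
{
  "record_id": "3",
  "category": "microalbuminuria",
  "stage": "2",
  "risk": "moderate",
  "gfr": 63.8031550068587,
  "gfr_displayed": 63.8,
  ...
}
Moderate risk of CKD development. A face-to-face consultation with a physician is recommended.
```

The chain behind that output: 77.5 mg/g ∈ [30, 300) → microalbuminuria;
clearance 63.8 ∈ [60, 90) → stage 2; grid cell (stage 2, microalbuminuria)
→ moderate risk. The same chain drives the exhaustive enumerator
(`ckdkit enumerate`), which tabulates all 18 terminal classifications over
the 4 risk levels.

Simulate a 60-subject, 4-rater panel at a design kappa of 0.7 and report
agreement:

```console
$ ckdkit simulate raters --n 60 --seed 11 --design-kappa 0.7 --out r.csv
wrote 60 x 4 ratings to r.csv
$ ckdkit kappa --input r.csv
Category,Kappa,CI low (95.0%),CI high (95.0%),Interpretation
High risk,0.7249,0.4806,0.9693,substantial
Low risk,0.7236,0.5475,0.8996,substantial
Moderate risk,0.5237,0.2701,0.7773,moderate
Very high risk,0.8947,0.7283,1.0612,almost perfect
Global Kappa,0.6970,0.5485,0.8454,substantial
```

Per-category rows are one-vs-rest kappas averaged over all rater pairs; the
global row is the mean pairwise Cohen's kappa (0.6970 here, close to the
0.7 design). Confidence bounds are deliberately not clipped to [−1, 1],
which is why a tight category can show an upper bound above 1.

The same operations are available as a library:

```python
from ckdkit import estimate_gfr, run_workflow, Gender

estimate_gfr(60, 80, 0.54, Gender.FEMALE).displayed   # 139.9
state = run_workflow(200.0, 50.0)
(state.category.value, state.stage.value, state.risk.value)
# ('microalbuminuria', '3a', 'high')
```

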