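# Methods

## Scope and model

`ckdkit` is a desk-scale decision core for early detection and
self-monitoring of chronic kidney disease (CKD). CKD is defined by a reduced
glomerular filtration rate (GFR) and by protein (albumin) excretion in urine;
the toolkit therefore chains three elementary classifications into one
deterministic workflow:

1. **Albuminuria verification.** The albumin-to-creatinine ratio (mg/g) is
   mapped to *normal* (< 30), *microalbuminuria* ([30, 300)) or *albuminuria*
   (≥ 300). The published cut-offs "between 30 and 299" are interpreted as the
   half-open interval [30, 300) on the real line so that no value is
   unclassifiable.
2. **GFR estimation and staging.** Clearance is estimated with the
   Cockcroft-Gault equation, C = (140 − I)·K / (72·P), with I age (years),
   K weight (kg), P plasmatic creatinine (mg/dL), multiplied by 0.85 for
   women. Cockcroft-Gault is used rather than MDRD-family equations because
   it needs no race coefficient, which is problematic to assign in admixed
   Latin American populations. Stages follow the KDIGO bands, half-open and
   owned by the less-severe stage: ≥ 90 → 1, [60, 90) → 2, [45, 60) → 3a,
   [30, 45) → 3b, [15, 30) → 4, < 15 → 5, so a GFR of exactly 90 is stage 1.
3. **Risk stratification.** An 18-cell (stage × albuminuria) grid in the
   KDIGO heat-map style assigns one of four ordered risk levels. Default
   grid: stages 1–2 → {low, moderate, high}; 3a → {moderate, high, very
   high}; 3b → {high, very high, very high}; 4 and 5 → very high throughout.
   The grid ships as configuration data; at load time it is checked to be
   total (all 18 cells) and monotone (risk never decreases as either axis
   worsens). A non-monotone override is possible but warns.

Driving the chain over every category × stage combination enumerates exactly
18 terminal classifications over exactly 4 risk levels (2 low, 3 moderate,
4 high, 9 very-high cells); each single evaluation produces exactly one of
them. Comorbidity flags (diabetes mellitus, systemic arterial hypertension)
and serum biomarker flags (creatinine 0.6–1.4 mg/dL, urea 20–40 mg/dL,
potassium 3.5–5.5 mEq/L, closed intervals, endpoints normal) annotate the
narrative but never alter the grid outcome; whether uncontrolled
comorbidities should escalate the reported risk is left to the physician, so
the engine reports them side by side.

### Display convention

Clearances are *truncated* toward zero at one decimal for display
(155.774… → 155.7). Truncation, not rounding, is the only convention
consistent with all recorded clearances in the reference cohort rows the
test-suite uses as oracles; the full-precision value is always carried
alongside.

### Evaluability

A record is evaluable only when creatinine, proteinuria, age, weight and
gender are present. Anything less raises an explicit "incomplete panel"
refusal — never a partial evaluation. This matters in practice: proteinuria
is missing from the majority of paper charts in the settings this tool
targets.

## Screening reminders

The next screening date is the evaluation timestamp plus a risk-dependent
interval, by default {low: 12, moderate: 12, high: 6, very high: 3} months.
The intervals are configuration, constrained to be monotone (higher risk
never waits longer). Month arithmetic clamps to month length (Aug 31 + 6
months → Feb 28/29).

## Self-monitoring

Blood pressure is *above target* when systolic ≥ 140 or diastolic ≥ 90 mmHg
(inclusive thresholds). Glucose targets are context-specific: preprandial
70–130 and fasting 70–99 mg/dL inclusive, postprandial < 180 mg/dL with a
strict upper bound and no lower bound. All cut-offs live in configuration:
guideline editions move, deployments differ, and nothing in the code depends
on the specific numbers. Sensor ingestion is a tagged-item stream interface
(no radio code); a sensor reading is classified by exactly the same path as a
manual one.

## Agreement statistics

Cohen's kappa between two raters is k = (p_o − p_e)/(1 − p_e), with p_o the
fraction of subjects rated identically and p_e = Σ_c m₁(c)·m₂(c) the
chance agreement from the raters' marginal label frequencies. Kappa is
undefined when p_e = 1 (both raters constant with the same label); this
surfaces as a typed error, never NaN.

* **Per-category kappa** collapses labels to category-vs-rest, computes the
  pairwise kappas over all rater pairs, and averages them. Pairs in which
  neither rater ever uses the category are skipped (their binary columns are
  identically zero and carry no information); the undefined signal fires only
  when no rater uses the category at all.
* **Global kappa** defaults to the mean of all pairwise Cohen kappas.
  Fleiss' kappa (via `statsmodels`) is available as a labeled alternative.
  Several multi-rater pooling conventions exist in the applied literature
  and reports rarely state which was used, so both are exposed and the
  result's `method` field always says which produced it.
* For multi-pair results, the reported p_o and p_e are pairwise means and
  the kappa is the mean of pairwise kappas; the algebraic identity
  k = (p_o − p_e)/(1 − p_e) is exact only for a single pair.
* **Confidence intervals** are the large-sample 95% Wald form,
  k ± 1.96·√(p_o(1 − p_o)/(n(1 − p_e)²)), with no bias or prevalence
  adjustment. Bounds are deliberately not clipped to [−1, 1]: clipping would
  misstate the sampling width, and published concordance tables in this
  application area print upper bounds above 1.
* **Interpretation scale:** absence (k ≤ 0), slight (0, 0.20], fair
  (0.20, 0.40], moderate (0.40, 0.60], substantial (0.60, 0.80], almost
  perfect (> 0.80). The conventional scale leaves (0, 0.01) and 1.0
  unlabeled; the intervals here are closed on the right and extended to 1 so
  every finite kappa has a label.

The implementation is plain marginal arithmetic on integer-coded ratings;
tests cross-check it to 1e-12 against an independently written
contingency-table oracle and against `sklearn.metrics.cohen_kappa_score`,
and the Wald width against a nonparametric bootstrap.

## Synthetic data

### Cohorts

`generate_cohort` emulates the screening cohort the toolkit targets:
systemic arterial hypertension prevalence 0.945, diabetes among
hypertensives 0.5882, every subject carrying at least one of the two
comorbidities by default, ages uniform on [31, 79] years. Lab values come
from truncated parametric families (weights and potassium/urea truncated
normal; creatinine and proteinuria lognormal, right-skewed so the deep
stages are reachable). **These distributions are synthetic conveniences,
not epidemiological estimates**: passing tests show the decision machinery
is correct on records shaped like real ones, not that the cohort mimics any
population's joint lab distribution, covariate correlations, or
longitudinal course.

With a `risk_mix`, generation inverts the workflow instead: a grid cell with
the requested risk is drawn, a GFR is sampled inside the stage band (with a
2% edge margin so value rounding cannot cross a band edge), the
Cockcroft-Gault equation is solved for the creatinine that produces it, and
a proteinuria is drawn inside the category range. This guarantees the
requested outcome mix exactly and lets a full-coverage mix exercise all 18
cells. Ground truth for every generated record is computed by the risk
engine itself at generation time.

### Rater panels

`simulate_raters` draws each rater's column from a confusion model around
known true risk labels. The default model is adjacent-category error —
with probability ε the rater reports a neighbouring ordered category
(interior categories split ε between both neighbours) — matching the
near-miss character of real inter-rater disagreement on ordered scales.
The expected pairwise kappa of two such raters has the closed form
p_o = Σ_t π_t Σ_d E[t,d]², p_e = ‖πᵀE‖², with π the truth mix and E the
emission matrix; `calibrate_adjacent_error` solves it for ε by bisection on
[0, 0.5]. The restriction matters: expected kappa is *not* monotone in ε
over [0, 1] — as errors become near-deterministic flips the raters start
agreeing with each other again — so calibration stays on the decreasing
branch, which under a uniform four-level truth mix covers designs down to
roughly κ ≈ 0.23. Alternative models: `resample` (with probability ε report
a draw from the truth marginal; expected kappa is exactly (1 − ε)²) and
`uniform` (truth-blind control with expected kappa 0).

A recovery study (4 raters, 60 subjects — the scale of the agreement study
this mirrors — 500 replicates per design) recovers design kappas 0.3–0.9
within 0.05 in the mean of the mean-pairwise estimator.

## Clinical documents

Documents are a small CDA-R2-like XML template under the fixed namespace
`urn:ckdkit:cda-lite:1`: header (patient demographics and comorbidity flags,
author id, effective time), then medications, allergies, lab results (every
entry carries a unit) and an optional risk-evaluation section. This is a
documented simplified template, not a conformant HL7 CDA implementation;
terminology binding is out of scope and transport is a file. Every built
document is validated against the shipped XML schema (`data/cda_lite.xsd`);
foreign-namespace sections survive a parse as opaque blocks. The effective
time is injected by the caller, so output is byte-deterministic —
`parse(build(d))` is an identity on the carried fields and is fuzz-tested.

## Numerical and design notes

* Band and interval boundaries: stage edges belong to the less-severe stage;
  biomarker reference intervals are closed; glucose upper bounds are closed
  except postprandial. All are configuration keys (see `ckdkit.config`).
* Medication/allergy alerting matches substances case-insensitively and
  exactly; the drug-interaction table is caller-supplied (no interaction
  knowledge is bundled), unordered, and alerting is order-independent and
  deduplicated.
* Randomness: a single integer seed drives `numpy.random.default_rng`
  everywhere; derived seeds stay below 2³¹.
* Problem sizes: the bundled studies use 60-subject panels with 500
  replicates and cohorts of up to 2000 subjects — the scale at which the
  estimator properties of interest are already visible while the whole suite
  runs in seconds.

## Known limitations

* The cohort generator does not model CKD progression over time, lab
  correlation structure, or measurement error.
* The mean-pairwise and Fleiss global kappas answer slightly different
  questions and will not agree numerically; neither is claimed to reproduce
  any particular published multi-rater value, since pooled results depend on
  the (often unstated) combination rule and the underlying ratings.
* Month-interval screening arithmetic is calendar-naive (no time zones).
* The CDA-lite template is intentionally minimal; it will not validate
  against official HL7 schemas.
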