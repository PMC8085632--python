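# Methods

## Attributable fractions

The core statistic is the population attributable fraction
PAF = P(RR−1)/(P(RR−1)+1), with P the exposed proportion and RR the
exposure–response measure. Three conventions matter and are applied
throughout:

* **Measure substitution.** Odds ratios and incidence-rate ratios enter
  the formula as if they were relative risks, with no rare-disease
  correction. The measure kind is carried as metadata
  (`measure_kind` ∈ {OR, RR, IRR}) so users can judge the
  approximation; for the respiratory outcomes involved the outcome
  prevalences are small and the OR≈RR distortion is second-order
  relative to the exposure-measurement uncertainty.
* **Truncation at zero.** Protective point estimates or lower confidence
  limits (RR < 1, e.g. the pneumonia lower CI of 0.78 under crowding)
  give a negative excess; the PAF is floored at 0 so attributable
  burdens are never negative.
* **Interval propagation.** Uncertainty ranges evaluate the formula at
  the paired lower and upper 95% limits of (P, RR). This brackets the
  estimate but is not a sampling distribution: it ignores the joint
  distribution of P and RR and is conservative at both ends. It is the
  only construction that is fully determined by printed inputs, and it
  reproduces the reference ranges (exactly where the exposure CI is
  degenerate, within one terminal digit elsewhere).

Attribution always multiplies by the **unrounded** PAF; rounding
(half-up; one decimal for percentages and deaths, whole units for
counts, costs and nights) is applied only in the display layer. Using a
pre-rounded percentage is a real failure mode — with the COPD fraction
rounded to 0.7%, 1555 annual deaths would print 10.9 attributable
instead of 10.5 — and is covered by a regression test.

## Registry and classification

The registry (YAML, shipped as package data, editable) holds per
condition: exposure estimates with CIs (stratified by age for crowding:
14.9% for under-6 disorders, 12.5% for under-17/under-19, 10.1%
otherwise), and per disorder: an ICD-10-AM pattern set, an optional age
restriction, the exposure–response measure with CI, a display group and
calibration targets.

Pattern dialect: bare codes are exact prefixes (`J45` covers `J45.0`),
`A–B` tokens are ranges over three-character categories, and
single-digit endpoints are zero-padded so `A0-A9` means the decade
A00–A09 (anything wider would swallow the tuberculosis block A15–A19).
Within a condition a code resolves to at most one disorder: longer
prefixes beat shorter, exact prefixes beat ranges of equal length,
registry order breaks remaining ties, and identical duplicated patterns
are rejected at load time. Classification is code-first: a code that
matches a disorder whose age restriction excludes the patient falls
through to the next candidate (and to the next admission's diagnosis).

Design choices where the source material is open:

* The damp-housing chapter-J "respiratory infections" group (one shared
  OR of 1.44) is sub-partitioned into report categories — URTI J00–J06,
  pneumonia/LRTI J09–J18+J22, bronchiolitis J21, bronchiectasis J47,
  remainder "other" — all carrying the shared measure. Asthma (J45–J46),
  bronchitis (J20, J40–J42), wheeze (R061–R062) and cough (R05) keep
  their own measures and take precedence.
* Emphysema/COPD (J43–J44) is excluded from the damp chapter-J group:
  COPD is not a respiratory infection, it is analysed under cold
  housing, and including it would multiply the damp "other respiratory
  infection" mortality several-fold past its reference value.
* Chronic rheumatic heart disease uses the standard I05–I09 block
  (the source table lists only I00–I02 for rheumatic fever, while the
  outcome tables report acute and chronic rows separately).
* Influenza (J09–J11) precedes pneumonia/LRTI (J09–J13, …) under
  crowding, so the overlapping codes resolve to the diagnostically
  specific disorder.
* Conditions are deliberately *not* mutually exclusive with each other:
  the same influenza admission counts toward crowding, cold and damp
  tallies, mirroring separate-condition reporting; per-condition burdens
  are therefore not additive.

## Episodes

Admissions of one patient merge into an episode when a re-admission
starts within 7 whole days of the episode's latest discharge (same-day
transfer merges; chaining is transitive). Nights are calendar days
between admission and discharge, so same-day discharges contribute zero
nights — necessary for outcomes like wheeze whose mean stay is below
one night. The episode's year is the year of its first admission, its
disorder comes from the primary diagnosis (`diag1`) of its first,
second, then third admission — the fallback walks across admissions,
not across the secondary diagnosis fields of one admission — and its
age is the age at first admission. The vectorized implementation
(within-patient running maximum of discharge dates) is verified against
an independent O(n²) union-find transitive closure on randomized small
registers. Exact duplicate records are dropped; records with admission
after discharge or negative cost are rejected and logged.

Annual summaries count patients distinctly within (condition, disorder,
year); a patient hospitalized under two disorders counts once in each.
Means divide by the configured span length (2010–2017 for
hospitalizations, 2010–2014 for deaths, 2010–2017 for claims — three
independent configuration values).

## Synthetic registers and calibration

The generator emulates the confidential source registers. Expectation
mode emits, per (disorder, year), exactly the rounded expected number
of single-admission episodes: patients are assigned round-robin so the
distinct-patient count matches its target, episodes of one patient are
spaced more than 7 days apart, nights are distributed integrally so the
annual total is exact, and costs are uniform so the annual total is
exact. Stochastic mode draws Poisson counts and nights, exponential
costs, optional within-7-day readmissions (which the episode builder
must re-merge) and a small fraction of non-classifiable noise records.
Only aggregate annual means are specified by the study design, so the
exponential cost law is a modelling convenience, not an inference.

Calibration back-derives population-level hospital means as
published attributable value ÷ unrounded PAF. Death and claim rates are
published directly at population level. Because diagnosis patterns
overlap across conditions, the death register uses an overlap-resolved
allocation over disjoint code pools (influenza codes carry the crowding
mean and simultaneously feed the cold and damp categories; remainders
go to condition-unique codes; all records at age 70, outside every
child-specific restriction), and golden-table admission registers are
generated per condition. Claims registers for golden runs cover a
single year — expectation mode is year-identical, so the annual mean is
unchanged while the register stays small.

Generated diagnosis codes are drawn from the pattern-expanded code sets
filtered through a classification round-trip; for catch-all patterns
this can include category codes with no clinical counterpart (e.g. J07),
which is acceptable for synthetic data but means the registers are not
clinically realistic code-frequency distributions. Other features of
real registers the generator does not emulate: seasonality, age and
cost heterogeneity within disorders, secondary diagnoses, and
between-year trends. Passing golden tests therefore demonstrates the
correctness of the pipeline arithmetic and plumbing, not the
plausibility of any particular register.

## Claims and mortality costing

Claims are kept when scene = home, cause = fall, the claimant is a
resident and the severity label is one of the six known categories
(unknown labels are rejected and logged). The default falls PAF is
0.2444 — the ratio implied by every attributable cell of the reference
claims table — with the narrative figure of 26% stored alongside and
selectable as an override. Attributable fatal falls feed the mortality
grand total. The societal mortality cost is the unrounded total of
attributable deaths times the VSL (NZ$ 4.2 million, June 2017; a
configured scalar — no wage indexation is implemented), converted to
US$ at 0.7148.

## Numerical conventions and degenerate inputs

Half-up rounding at display only; counts below one print with one
decimal. Empty registers produce empty (all-zero) tables, not errors.
Scale 0 in the generator produces empty registers. PAF inputs outside
their domains, negative totals, inverted CI bounds, malformed ICD
tokens, unknown severities and invalid generator configurations raise
errors naming the offending field. Seeded generation is byte-identical
across runs.

## Problem sizes

Golden reproduction uses the full back-derived scale: roughly 15 000
crowding, 14 000 cold and 51 000 damp admissions per year over eight
years (≈ 650 000 records), ≈ 2 800 deaths per year over five, and one
year of ≈ 473 000 claims; the complete run takes a few seconds.
Stochastic property tests use reduced rates or a global scale factor,
which is legitimate because attribution is linear and the generator's
law scales cell-wise.

## Known limitations

* The interval propagation understates/overstates nothing about
  correlation between P and RR because none is modelled; ranges are
  heuristic brackets.
* No interaction or comorbidity modelling: per-condition burdens
  overlap and must not be summed across conditions.
* The reference totals that are internally inconsistent in the source
  material (a crowding total excluding its own influenza row; a grand
  death count and mortality cost that disagree with their printed
  components) are *not* special-cased: the pipeline reports true column
  sums, so its crowding totals and grand totals differ from the
  reference by exactly those discrepancies.
* Exposure prevalences are self-reported and likely conservative;
  nothing in the pipeline corrects for under-reporting.
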