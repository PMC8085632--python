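# housingburden

Environmental burden-of-disease estimation for substandard housing:
a tested, reusable pipeline that computes the share of hospitalizations,
hospital nights, costs, deaths and injury claims attributable to four
adverse housing conditions — household crowding, cold housing, damp or
mouldy housing, and home injury hazards linked to falls — from
record-level registers.

## Who this is for

Public-health analysts doing comparative risk assessment at the national
level. The reference setting is New Zealand 2010–2017 (publicly funded
hospitalizations, mortality records to 2014, and no-fault accident
compensation claims), but every input — exposure prevalences, exposure–
response measures, diagnosis code sets, age restrictions, spans, the
value of a statistical life, the exchange rate — lives in an editable
YAML registry, so the pipeline transfers to other settings.

## The model

For each health disorder linked to a housing condition, the population
attributable fraction is

```
PAF = P (RR − 1) / (P (RR − 1) + 1)
```

where *P* is the proportion of the population exposed to the condition
and *RR* the exposure–response measure (odds ratios and incidence-rate
ratios are substituted directly, without rare-disease correction;
protective values floor the PAF at zero). Uncertainty ranges evaluate
the formula at the paired 95% confidence limits of *P* and *RR*.

Attribution multiplies *unrounded* PAFs by population-level annual means
built from record-level registers:

* **Hospitalizations** — admissions of one patient merge into a single
  *episode* whenever a re-admission occurs within 7 days of the prior
  discharge; each episode is assigned one disorder per condition by
  walking the primary diagnoses (ICD-10-AM) of its first three
  admissions; annual counts of episodes, distinct patients, nights and
  costs are averaged over the span and attributed per disorder.
* **Deaths** — classified by underlying cause of death with the same
  registry, averaged over the mortality span, attributed, then costed
  with a willingness-to-pay value of a statistical life
  (NZ$ 4.2 million, June 2017).
* **Injury claims** — home-scene resident fall claims in six severity
  categories, attributed with a single falls PAF (default 0.2444).

The real registers are confidential, so the package ships a synthetic
generator whose deterministic "expectation mode" can be calibrated by
back-derivation (population mean = published attributable value ÷ PAF)
to reproduce the published tables end to end.

## Worked example

```python
from housingburden import Registry, compute_paf, reproduce_printed

registry = Registry.load()

# attributable fraction for cough under damp or mouldy housing
paf = compute_paf(p=0.318, rr=1.67)
print(f"damp-housing cough PAF: {100 * paf:.1f}%")

# full reproduction of the attributable tables on calibrated synthetic registers
bundle = reproduce_printed(registry=registry)
cold = bundle.table_hospital.query("condition == 'cold'")
print(f"cold housing: {cold['hospitalizations'].sum():.0f} hospitalizations/yr, "
      f"{cold['nights'].sum():.0f} nights, NZ$ {cold['cost_nzd'].sum():,.0f}")
gt = bundle.grand_totals
print(f"direct public-sector cost: NZ$ {gt['direct_cost_nzd'] / 1e6:.1f} million "
      f"(US$ {gt['direct_cost_usd'] / 1e6:.1f} million)")
print(f"total attributable deaths: {gt['total_deaths']:.1f}/yr "
      f"-> societal cost NZ$ {gt['mortality_cost_nzd'] / 1e6:.1f} million")
```

prints

```
damp-housing cough PAF: 17.6%
cold housing: 625 hospitalizations/yr, 1834 nights, NZ$ 2,313,378
direct public-sector cost: NZ$ 142.0 million (US$ 101.5 million)
total attributable deaths: 230.8/yr -> societal cost NZ$ 969.5 million
```

The cough PAF says 17.6% of cough hospitalizations would be avoided if
exposure to damp or mouldy housing were eliminated. The cold-housing
line is the attributable hospital burden (episodes, nights, 2017–2018
NZ$ cost) recovered by running the full pipeline on calibrated
registers. The grand totals combine attributable hospitalization costs
with attributable claim costs, and value all attributable deaths
(including fatal falls) at the VSL. Because the conditions overlap in
real homes, per-condition burdens are tallied independently and are not
simply additive.

## Command line

```
housingburden generate  --out-dir registers --seed 1 --mode stochastic --scale 0.01
housingburden calibrate --condition cold --out cold.json
housingburden run       --admissions registers/admissions.csv \
                        --deaths registers/deaths.csv \
                        --claims registers/claims.csv --out-dir report
housingburden tables    --out-dir report   # calibrated golden reproduction
```

Register schemas (headed CSV, ISO-8601 dates):

| register | columns |
| --- | --- |
| admissions | `patient_id, admit_date, discharge_date, diag1, diag2, diag3, age_years, cost` |
| deaths | `underlying_cause, year, age_years` |
| claims | `scene, cause_class, resident, severity, cost, year` |

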