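# graftval

Early liver-allograft function scores and survival-discrimination validation
tooling, with a seeded synthetic post-transplant cohort generator.

The package computes, from post-operative laboratory trajectories (AST, ALT,
total bilirubin, INR, platelets on post-operative days 1–10):

* the dichotomous **early allograft dysfunction** criteria (POD-7 bilirubin
  ≥ 10 mg/dL, POD-7 INR ≥ 1.6, or peak ALT/AST > 2,000 IU/L in the first
  week),
* the continuous **3-day sigmoid-sum score** (sum of three sigmoid-transformed
  lab values, range (0, 9.98]),
* the **7-day and 10-day graft-assessment scores** (polynomials in AUC and
  slope of log lab trajectories),
* the **simplified-estimation score** (MELD, transfusion volume, vessel
  thrombosis, trajectory features, center volume),

assigns each score's published risk groups (including the 7-day score's
high/low dichotomy), and runs the validation analyses: binary 3/6/12-month
graft- and patient-survival endpoints, AUROC with DeLong variance and paired
DeLong tests between all model pairs, Kaplan–Meier curves with log-rank tests
per risk class, and a univariable screen → collinearity filter →
multivariable logistic regression for high-risk-group membership.

Because the motivating clinical cohort is not publicly available, the
`synthetic` module generates reproducible cohorts with the statistical
structure the analysis assumes (severity-linked lab trajectories, POD 8–10
missingness, death/retransplant/censoring outcomes), so every stage is
testable end to end.

## Layout

| module | contents |
| --- | --- |
| `graftval.cohort` | domain types, canonical units, CSV readers/writers, eligibility filter |
| `graftval.features` | trapezoid AUC / OLS slope of (log-)lab curves, per-model feature bundles, coverage rules |
| `graftval.scores` | the five scoring systems and their risk bins |
| `graftval.survival` | horizon labels, Kaplan–Meier, log-rank |
| `graftval.discrimination` | AUROC, DeLong variance/CI, paired DeLong test, model comparison matrix |
| `graftval.riskfactors` | univariable screen, multicollinearity filter, multivariable logistic |
| `graftval.synthetic` | seeded cohort generator + hand-constructed known-answer fixtures |
| `graftval.pipeline` / `graftval.cli` | end-to-end driver and `graftval` command-line interface |

## CLI

```sh
# write a synthetic cohort (labs.csv, clinical.csv, config echo)
graftval simulate --n 800 --seed 7 --out sim/

# scores only
graftval score --labs sim/labs.csv --clinical sim/clinical.csv --out out/

# full study: exclusions, scores, AUROC/DeLong tables, KM by risk class,
# risk-factor tables
graftval run-all --labs sim/labs.csv --clinical sim/clinical.csv --out out/
# ... or in one step from the generator
graftval run-all --simulate-n 800 --seed 7 --out out/
```

Useful flags: `--horizons 90,180,365`, `--censored-as-survivor` (count
patients censored before a horizon as survivors instead of excluding them),
`--auc-normalized` (time-averaged AUC features instead of the default
unnormalized trapezoid), `--screen-p` (univariable screen threshold,
default 0.1).

Input formats: a long labs CSV (`patient_id,pod,analyte,value,unit`; bilirubin
may be given in µmol/L and is converted to mg/dL) and a one-row-per-patient
clinical/outcome CSV (covariates, 0/1 exclusion flags,
`follow_up_days`/`death`/`death_day`/`retransplant`/`retransplant_day`).
`graftval simulate` writes examples of both.

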