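# spousesim

Spouses resemble each other in cardiometabolic risk factors — blood
pressure, lipids, smoking, hypertension, metabolic syndrome.  But spouses
are also close in age, and nearly every one of these risk factors changes
with age, so part of any observed spousal similarity is an artefact of age
alignment rather than of assortative mating or of living together.
`spousesim` implements the analysis design that separates the two: keep the
husbands, and re-pair each one with a randomly chosen woman of *exactly his
wife's age*.  Whatever similarity survives in these random male–female
pairs is attributable to age structure alone; whatever similarity spouse
pairs show beyond it reflects couple-specific (environmental) factors.

The package is aimed at epidemiologists working with couple cohorts.  Since
such data are typically access-restricted, it ships a calibrated synthetic
couple-cohort generator so the whole pipeline is runnable and testable
end to end.

## What it computes

- **Exact-age-matched re-pairing.**  Women are grouped into strata of
  identical integer age and permuted within each stratum (Fisher–Yates,
  seeded).  The multiset of (male age, female age) pairs — and hence the
  spousal age correlation — is preserved *exactly*.
- **Similarity of continuous traits.**  For paired values
  (x_i, y_i), the Pearson correlation r with Fisher-z confidence limits
  tanh(atanh(r) ± z_{1−α/2}/√(n−3)); and an *age-adjusted* version that
  correlates residuals from sex-specific OLS regressions of the trait on
  age.  Triglycerides are log10-transformed.
- **Concordance of binary traits.**  Logistic regression of the male's
  status on his partner's status; the exponentiated coefficient is the
  concordance odds ratio (Wald CIs).  The age-adjusted model adds the pair
  mean age and the male−female age difference as covariates.
- **Harmonization.**  BMI, Friedewald LDL (TC − HDL − TG/5, TG < 400
  mg/dL), treatment back-adjustment (+15/+10 mmHg to treated SBP/DBP;
  treated TC/LDL divided by 0.8/0.7), mean ± 5 SD outlier exclusion per
  variable per sex, hypertension / type 2 diabetes / metabolic-syndrome
  flags (Japanese criteria), education recode, and a physical-activity
  cut-off at the 80th percentile of the men's MET·hours/day.
- **Synthetic cohorts.**  Correlated integer spousal ages; per-trait
  sex-specific means, SDs and age slopes; a per-couple latent factor with
  residual correlation `couple_corr`; a couple effect `couple_log_or` on
  the log-odds scale for binary habits; thresholded medication assignment
  with treatment-attenuated measurements; MCAR missingness per variable.

## Worked example

```python
import spousesim as s

cfg = s.default_config().model_copy(update={"n_pairs": 2000})
cohort = s.generate_cohort(cfg, seed=42)          # spouse-paired couples
derived = s.derive_all(cohort)                    # analysis variables
random_pairs = s.exact_age_shuffle(cohort, seed=42)

spouse = s.SpousalSimilarity(derived, cohort.pairs,
                             variables=["age", "height", "sbp", "tg"]).fit()
random = s.SpousalSimilarity(derived, random_pairs.pairs,
                             variables=["age", "height", "sbp", "tg"]).fit()
print(spouse.summary())
print(random.summary())
```

prints

```
Spousal similarity: Pearson correlations with 95% Fisher-z CIs
variable       n  simple r (CI)               age-adjusted r (CI)
age         2000  0.932 (0.926, 0.937)        NA
height      2000  0.172 (0.129, 0.214)        0.123 (0.080, 0.166)
sbp         1802  0.155 (0.110, 0.200)        0.073 (0.027, 0.119)
tg          1994  0.113 (0.069, 0.156)        0.122 (0.078, 0.165)

Spousal similarity: Pearson correlations with 95% Fisher-z CIs
variable       n  simple r (CI)               age-adjusted r (CI)
age         2000  0.932 (0.926, 0.937)        NA
height      2000  0.058 (0.015, 0.102)        -0.001 (-0.045, 0.043)
sbp         1804  0.096 (0.050, 0.142)        0.001 (-0.046, 0.047)
tg          1994  0.001 (-0.043, 0.045)       0.009 (-0.035, 0.053)
```

Read it like this: the age correlation is identical in the two pairings by
construction of the shuffle.  Spouse pairs show residual similarity in
height, SBP and triglycerides even after age adjustment (the injected
couple effects).  Random pairs retain a *simple* SBP correlation of about
0.10 — driven purely by the age trend of blood pressure in both sexes —
which vanishes once age-adjusted.  The concordance side shows the same
pattern:

```python
conc = s.SpousalConcordance(derived, cohort.pairs,
                            outcomes=["current_smoker", "hypertension"]).fit()
print(conc.summary())
```

```
Partner concordance: logistic ORs with 95% Wald CIs
outcome                  n  crude OR (CI)                 age-adjusted OR (CI)
current_smoker        1925  5.58 (3.54-8.80)***           5.50 (3.47-8.70)***
hypertension          1717  1.45 (1.18-1.78)***           1.22 (0.98-1.51)
```

while on the random pairing hypertension drops from a crude OR of 1.18 to
an age-adjusted 0.97 — age-driven concordance that the adjustment removes.

There is also a CLI mirroring the library
(`spousesim simulate | derive | shuffle | analyze | report | all`), e.g.

```sh
spousesim all --seed 1 --outdir output
```

which writes the cohort CSVs, both pairings' descriptive, correlation and
concordance tables, and a JSON run log.

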