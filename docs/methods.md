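# Methods

## The question and the design

Observed spousal similarity in a cardiometabolic trait mixes three sources:
assortative mating (partners were alike to begin with), cohabitation
effects (partners converge while living together), and *age alignment* —
spouses are close in age, and most cardiometabolic traits trend with age,
so even randomly matched men and women of similar ages would correlate.
The package implements the permutation design that isolates the third
source: within strata of identical integer female age, wives are randomly
reassigned to husbands.  The re-paired cohort has exactly the original
joint age distribution (the (male age, female age) multiset is invariant,
so the age correlation is preserved to machine precision) but no
couple-specific structure.  Estimates on the random pairing quantify the
age-driven component; spouse-pair estimates in excess of it quantify the
couple-specific component.

Two complementary adjustments attack the same confounder analytically:
for continuous traits, correlating sex-specific OLS age-residuals; for
binary traits, adding pair mean age and male−female age difference to the
logistic concordance model.  The signature result is a trait whose crude
estimate is clearly positive on the random pairing while its age-adjusted
estimate is null; the test suite constructs such cohorts explicitly.

## Statistical machinery

- **Correlations.**  Sample Pearson r over pairwise-complete pairs; CI
  `tanh(atanh(r) ± z/√(n−3))`.  The same n−3 formula is used for the
  residual correlation, without a degrees-of-freedom correction for the
  two fitted age regressions — an approximation, adequate at the intended
  sample sizes (thousands of pairs; the correction would change √(n−3) by
  a part in ~n).  Inputs landing within 1e−15 of |r| = 1 are snapped to ±1
  and given a degenerate point interval.
- **Age residuals.**  OLS of value on age with intercept, fitted per sex
  over exactly the individuals entering that variable's analysis (post
  missingness, outlier and eligibility filtering).  Residuals of residuals
  equal residuals, and residuals sum to zero; both are asserted.
- **Concordance.**  Maximum-likelihood logistic regression (statsmodels
  `Logit`), Wald CIs on the log-odds scale.  On a saturated (exposure-only)
  model the OR equals the 2×2 cross-product ad/bc; an independently
  hand-coded cross-product-plus-Woolf-CI routine serves as the oracle for
  that equivalence.  Separation or non-convergence raises rather than
  returning a numerically meaningless estimate; no continuity correction is
  applied to sparse tables.
- **Group tests** (descriptive table): pooled-variance Student t for
  continuous variables, Mann–Whitney U (normal approximation with tie
  correction) for triglycerides, Pearson chi-square without continuity
  correction for categorical variables.  Rounding happens only at the
  reporting layer.

## Harmonization rules

BMI = weight / (height/100)².  Friedewald LDL = TC − HDL − TG/5, treated as
missing at TG ≥ 400 mg/dL (the standard validity bound; configurable); in
`derive_all` it only fills records whose measured LDL is absent.  Treated
individuals' measurements are back-adjusted to approximate untreated values
before correlation analysis: +15/+10 mmHg to SBP/DBP under antihypertensive
medication, TC/0.8 and LDL/0.7 under lipid-lowering medication.  Disease
flags use raw measured values, never the back-adjusted ones.  HbA1c
analyses exclude anyone on glucose-lowering medication.  Outlier screening
removes values beyond mean ± 5 SD, with mean and SD computed in a single
pass per variable per sex after treatment adjustment (the order is a
package choice; a single pass avoids iteration-order ambiguity); exclusion
blanks the derived analysis value and never the raw measurement, which
makes `derive_all` idempotent.  Disease flags follow three-valued logic: a
flag is missing exactly when the missing components could change the
verdict (a man with waist 84 cm is negative for metabolic syndrome
regardless of his other components, because the waist criterion is
mandatory).  The activity cut-off is the 80th percentile (linear
interpolation between order statistics) of the men's MET·hours/day, applied
to both sexes as `met_hours ≥ threshold`; the current-smoker and
current-drinker contrasts pool past and never users.

## The synthetic generator

One couple is simulated as:

1. **Ages**: bivariate normal with means 63.2/60.4 y, SDs 10.5/10.2 y,
   correlation 0.934; rounded to integer years (questionnaire granularity)
   and truncated below 20 y by resampling, not clipping, to avoid a point
   mass at the boundary.  Rounding attenuates the realized correlation by
   well under 0.001.
2. **Continuous traits**: value = sex mean + sex age-slope · (age − sex age
   mean) + couple term + noise.  The couple term is a per-couple standard
   normal scaled by √|ρ|·σ_resid (sign-flipped for one member if ρ < 0) and
   the noise by √(1−|ρ|)·σ_resid, with σ_resid chosen so the *marginal* SD
   equals the configured SD.  ρ (`couple_corr`) is therefore the residual —
   age-independent — within-couple correlation, and the age slopes acting
   on correlated ages generate the age-driven component on top of it.
   Triglycerides and MET·hours are modelled on the log10 scale and
   exponentiated.
3. **Binary habits**: the female status from her logistic age model; the
   male from his, plus `couple_log_or` × (female status).  Thus
   exp(`couple_log_or`) is exactly the age-conditional concordance OR the
   adjusted model estimates — which is what makes the type-I-error and
   parameter-recovery tests sharp.
4. **Medication**: treated with probability p when the pre-treatment value
   crosses a clinical threshold (SBP ≥ 140 / DBP ≥ 90, HbA1c ≥ 6.5,
   LDL ≥ 140 by default).  The *stored* measurement is attenuated by the
   same constants the harmonization back-adjustment adds back, so the
   inversion is exact by construction and testable.
5. **Missingness**: independent per variable (MCAR), at rates chosen to
   roughly reproduce the per-variable availability of the reference cohort
   (e.g. waist ≈ 59%, total cholesterol ≈ 36% available).  No mechanism
   beyond MCAR is modelled.

### Default calibration

Defaults are fixed to the descriptive statistics of a published Japanese
couple cohort of 5,391 spouse pairs: the age model above; trait means/SDs
per sex from its descriptive table (log-scale parameters for TG derived
from the printed medians and quartiles); smoking prevalence by age from its
reported age-group rates via a two-point logit fit; couple effects of the
same order as its spousal estimates (residual correlations ≈ 0.07–0.18,
couple log-ORs of log 4.6 for smoking and log 2.8 for drinking).  These are
study conditions, not tuning knobs.

### What the generator does *not* emulate

Traits are (log-)normal and linear in age; real HbA1c and waist
distributions have heavier right tails, so simulated disease prevalences —
especially diabetes and metabolic syndrome in women — run below the
reference cohort's, and disease-level concordance in the default cohort is
correspondingly weaker and noisier.  Missingness is MCAR, not related to
health status.  Couples share a single latent factor per trait; there is no
trait-to-trait coupling (beyond age) and no duration-of-marriage gradient.
Passing tests therefore demonstrate that the *estimators and the
permutation design* behave as claimed under known truth, not that the
generator reproduces any real cohort's effect sizes.

## Problem sizes and numerical choices

Calibration checks simulate 5,000–5,391 couples; the type-I-error property
uses 400 cohorts of 400 couples (rejection of the null by the adjusted
Wald CI is counted and compared with the nominal 5% ± 2 points); effect
injection uses 50 replicates per grid point at n = 400; parameter recovery
averages three replicates of n = 5,000 per injected correlation.  Shuffle
uniformity is checked by enumerating all six permutations of a three-woman
stratum over 6,000 seeded shuffles.  All simulation is seeded through
`numpy.random.default_rng`; strata are processed in ascending age order so
shuffles reproduce across platforms.

## Known limitations

- One BP measurement per person is assumed; replicate-measurement
  averaging is out of scope.
- The Fisher CI for adjusted correlations ignores the uncertainty of the
  age regressions (see above).
- A single randomization is the default, mirroring the design the package
  implements; Monte-Carlo spread across re-pairings can be quantified by
  calling `exact_age_shuffle` with multiple seeds.
- No imputation and no unit conversion beyond cm→m; lipid and glycaemic
  inputs are expected in mg/dL and %.
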