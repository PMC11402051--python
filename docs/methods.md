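# Methods

## Problem and scope

`bevmod` estimates beverage-intake trends across early childhood (ages
1–5 y) from single-day 24-h dietary recall micro-data collected under a
stratified multi-PSU survey design, and models two within-person dietary
scenarios for children aged 2–5 y: adding one cup of milk to each child's
day, and isocalorically replacing all nonmilk caloric beverages consumed at
lunch and dinner with milk. Because the motivating micro-data (NHANES/WWEIA
day-1 recalls) cannot be redistributed, the package ships a synthetic
recall generator with the same structure and known ground truth, so every
stage is testable end to end without any download.

## Data model

One recall day per subject. A subject carries demographics (age in whole
years 1–5, gender, a five-level ethnicity, a three-level poverty-income
ratio category) and design fields (positive survey weight, stratum, PSU,
with at least two PSUs per stratum). A food item carries an eating
occasion, an 8-digit food code, a 4-digit WWEIA category code, grams, and
an 18-component per-portion nutrient vector (energy kcal; carbohydrate,
fiber, total sugars g; added sugars tsp-eq; protein, total fat, MUFA, PUFA,
SFA g; calcium, magnesium, potassium, sodium mg; vitamin A μg RAE; folate
μg DFE; vitamin B-12 μg; vitamin D μg). Nutrients come from an FNDDS-style
per-100-g reference table, linear in grams.

Dairy rows in real nutrient databases report total sugars (lactose assay)
slightly above carbohydrate-by-difference; the reference-table validation
therefore allows total sugars to exceed carbohydrate by up to 0.25 g/100 g.
All other composition invariants (fat partition, fiber ≤ carbohydrate,
added-sugar grams ≤ total sugars) are enforced strictly.

## Beverage taxonomy

Categories key on prefixes of the 4-digit WWEIA code: milk = subgroup 10,
flavored milk = 12, milk substitutes = category 1404, 100% juice = 70,
SSB = 72 (soft drinks 7202, fruit drinks 7204 nested inside), coffee/tea =
73. "Caloric beverages excluding milk" (CB) is the whole beverage main
group with positive energy minus the water/diet/non-caloric subgroups (71,
77, 78); CB+M adds the milk family. Caloric categories match only items
with positive energy, so plain water and diet drinks are never classified
and zero-energy coffee/tea is ignored. The printed definition of CB in the
source coding scheme is ambiguous about its main-group number, so the whole
rule table ships as editable YAML; the default preserves the nesting
soft_drinks ⊆ ssb ⊆ cb ⊆ cb_plus_m, fruit_drinks ⊆ ssb, milk ∩ cb = ∅.

## Milk (nfs) profile

Both scenarios use "milk, not further specified" (food code 11100000), a
composite over fat levels, as a fixed per-cup vector with cup mass 225 g:
energy 122 kcal, protein 8.1 g, total fat 4.85 g (SFA 2.9), carbohydrate
12.0 g, total sugars 12.5 g, fiber 0, added sugars 0, calcium 290 mg,
magnesium 27 mg, potassium 358 mg, sodium 103.5 mg, vitamin A 123 μg RAE,
folate 11.5 μg DFE, B-12 1.14 μg, vitamin D 2.99 μg. These constants are
baked in so the package is self-contained; `MilkProfile` accepts a
substitute per-cup vector for users with a real FNDDS extract. Added sugars
are carried in tsp-eq; 4.2 g/tsp is used only for validation. The cup mass
affects gram bookkeeping only, never the per-cup nutrient arithmetic
(`energy_density = 122/225 kcal/g`).

## Survey estimation

All population quantities use the population ratio method: the per-capita
mean Σwᵢxᵢ/Σwᵢ over consumers and nonconsumers alike. Variances are
Taylor-linearized under the with-replacement stratified first-stage
approximation (standard for NHANES-style designs; no finite-population
correction): for linearized variate z, var = Σ_h n_h/(n_h−1) Σ_j
(t_hj − t̄_h)² with t_hj the weighted PSU totals. A stratum contributing a
single PSU raises an explicit error naming the stratum. Degrees of freedom
are PSUs − strata and p-values use the t distribution at that df (the SAS
survey-procedure convention). Multi-cycle weight construction (dividing
single-cycle weights by the number of combined cycles) is the caller's
responsibility; estimation treats weights as given.

Age trends come from survey-weighted least squares of the outcome on
continuous age, adjusted for gender, ethnicity and PIR category
(dummy-coded; reference levels male / non-Hispanic white / PIR > 1.85 —
the largest groups, affecting intercepts only, never the age coefficient).
The covariance is the linearized sandwich (X'WX)⁻¹ S (X'WX)⁻¹ with S the
stratified between-PSU covariance of the score totals. Per-age adjusted
means are predicted marginal means from a saturated-age model at the
observed (weighted) covariate distribution; with no covariates they reduce
exactly to per-age weighted means. Equal-margins weighting is not offered;
observed-margins is the only and default choice.

The paired scenario test is identical to a one-sample design-based test on
the per-subject differences: weighted mean difference, linearized SE,
two-sided t p-value, significance at P < 0.01 (configurable). Two
degenerate cases are handled explicitly: constant differences give SE 0
(flagged; p → 0 unless the difference is zero), and differences at
floating-point noise level relative to the data scale (≤ 1e-9 of the
largest baseline value) are reported as no change, p = 1 — this is what
the isocaloric scenario's energy row produces by construction.

## Synthetic generator

The generator is a first-class module, not a fixture. Defaults encode the
observed study conditions: 1800 subjects per age (9000 total, near the
9099 of the motivating pooled sample), 15 strata × 2 PSUs with lognormal
weights (σ = 0.5) normalized to a 4-million population, and demographics
from the observed age-2 distribution (16.5% Mexican American, 54.3%
non-Hispanic White, 13.7% non-Hispanic Black, 49.3% PIR > 1.85, ...).
Stratum×PSU cells are filled round-robin within each age group so per-age
analyses retain the full design.

Each beverage category follows an age-linear mean gram model
m(a) = intercept + slope·(a−1) with the observed age-1 means as intercepts
and the published per-year regression coefficients as slopes (milk 487 g,
−60.4 g/y; flavored milk 17.5, +14.8; milk substitutes 18.3, −3.01; 100%
juice 153, −10.2; fruit drinks 72.5, +16.0; soft drinks 16.5, +16.1; other
SSB 14.0, −0.3; coffee/tea 16.0, +3.07). These components are internally
consistent with the published composite categories (juice + SSB +
coffee/tea sum to the CB mean and slope exactly). Consumption is
zero-inflated: a Bernoulli daily-consumption indicator per category
(configurable probability), with consumers drawing Gamma(shape 4,
mean m(a)/p) grams — nonnegative and right-skewed like real intake data.
Categories are drawn independently; no within-subject correlation across
beverages is modeled. Occasions are drawn per item (milk spread across
meals, sweetened beverages weighted toward lunch/dinner/snack).

Non-beverage filler items (fortified cereal at breakfast, a pizza-style
lunch dish, a mixed dinner dish, fruit at snack) absorb the gap between
expected beverage energy and the age-linear total-energy target
(1289 kcal at age 1, +108 kcal/y), with Gamma(shape 8) noise. A
configuration whose expected beverage energy exceeds the energy target, or
whose category mean goes negative at any age, is rejected at validation.

What the generator does not emulate: day-2 recalls and usual-intake
(measurement-error) modeling, nonresponse and weight-calibration
methodology, within-person correlation across beverage categories, cycle-
specific nutrient profiles, and the occasion composition of real recalls
beyond the configured placement probabilities. Passing tests therefore
demonstrate correctness of the estimation and modeling machinery under a
faithful design structure, not agreement with any real population's intake
distribution.

## Scenarios

Both scenarios exclude age-1 children by default (low nonmilk caloric
beverage consumption at that age); the age set is configurable.

Scenario 1 adds `cups_added` (default 1) cups of milk-nfs to each child's
daily total. The adjusted−baseline difference is the per-cup vector for
every subject, so population means shift by exactly the per-cup vector
(weights cancel).

Scenario 2 pools the energy E of each subject's replaceable items
(default: CB ∪ milk substitutes at lunch or dinner with positive energy;
flavored milk stays unreplaced unless toggled; 100% juice is replaced by
default, exemptable) and substitutes milk-nfs with energy exactly E
(cups = E/122). Replacement is per subject-day rather than per item — for
linear nutrient accounting the result is identical, and it matches the
"all beverages at lunch and dinner combined" framing. Daily energy is
conserved to floating-point precision (≪ 1e-9 kcal). Replacement milk is
reported both as a mean over all subjects and over replacers only, since
either convention is defensible. Applying the substitution twice equals
applying it once (milk is never replaceable), and enlarging the replaced
set never decreases the milk added.

Eating occasions use the canonical enum {breakfast, lunch, dinner, snack,
other}; mapping survey-specific occasion codes (including Spanish-language
labels: almuerzo/comida → lunch, cena → dinner) onto this enum is left to
data preparation, as the generator emits canonical labels directly.

## Numerical choices and problem sizes

- Parameter-recovery checks run at n = 4000 per age; the Taylor-vs-
  jackknife comparison uses 50 random small designs (3–7 strata, 2–3 PSUs,
  4–9 subjects per PSU); null calibration of the paired test uses 2000
  simulated surveys of 100 subjects (10 strata × 2 PSUs), chosen to give a
  stable binomial check at the 0.01 level.
- Percent changes between the youngest and oldest age are rounded
  half-away-from-zero to integer percent, matching the reporting
  convention of the summaries they reproduce.
- The per-cup milk constants reproduce the published adjusted columns
  exactly at printed precision wherever the printed adjusted−baseline
  difference is constant across ages (energy, fiber, added sugars, SFA,
  calcium, magnesium, potassium, vitamin D); elsewhere printed-baseline
  rounding makes a one-unit-in-the-last-digit discrepancy unavoidable for
  any constant profile, and tests assert within one printed unit.
- Ties in gamma draws, weight normalization and cell assignment are all
  driven by one `numpy` Generator seeded from a single integer, so a fixed
  seed reproduces every output byte for byte (micro-data CSVs are written
  and re-read with round-trip float formatting).

## Known limitations

Single-day recalls cannot estimate usual-intake distributions; no
measurement-error model is applied. The modeled scenarios evaluate a
maximum effect (every replaceable beverage is replaced) and are not
behavioral predictions. LS-means use observed-margins weighting only. The
jackknife exists only as a test oracle; no replicate-weight variance
estimation is exposed.
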