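# Methods

This note documents the model, the synthetic data-generating process, the
numerical choices, and the limits of what the test suite demonstrates.

## Scope and design

The package models the cash-benefit ("allowance") side of long-term care
for the population aged 65 and over. Everything younger — fertility,
partnership, migration, schooling — is outside the model; its net effect
on the 65+ population is carried by an exogenous *entry schedule* (cohort
size and education composition of new 65-year-olds each January). This
keeps the contract small while preserving the two forces the scenario
analysis is about: longevity gains and educational expansion through
cohort replacement.

Time advances in discrete monthly steps. Care status is cross-sectional
by construction — levels are reassigned monthly from current prevalence
probabilities with no individual persistence — so a monthly discrete-time
engine observes exactly what a continuous-time engine would at the same
monthly resolution. Ages are stored in months; all prevalence and hazard
lookups use age at last birthday (integer years), because the statistics
being aligned to are by single year of age. Ages above 105 are pooled
into an open 105+ interval to keep cells populated.

## The assessment rules engine

Seven levels with exclusive hour bounds 65, 95, 120, 160, 180, 180, 180;
levels 5–7 additionally require one of three qualitative criteria
(extraordinary care; uncoordinated day-and-night care or permanent
day-and-night presence; no purposeful movements of the four extremities).
Classification returns the *highest* satisfied level, so 200 h without a
qualitative criterion stays at level 4, and multiple criteria resolve to
the highest level. Dementia adds 40 h/month to the assessed need *before*
classification, so the premium can push a person across a level boundary
(60 h + premium → level 2). The hour bounds are strict (`>65`), matching
the level criteria as printed rather than the looser "at least 65 h"
phrasing of eligibility summaries; an `inclusive` switch is provided. The
default payout schedule is the printed 2025 one (200.80 … 2156.60
EUR/month); the rule table is a configuration input so any vintage can be
substituted, and all monetary outputs are constant-price sums under
whatever fixed schedule is configured.

## Synthetic data generating process

The generators stand in for census microdata, an assessed-hours survey,
official mortality/cohort projections, and benefit statistics. They
emulate qualitative structure, not any country's numbers.

* **Population** (default n = 10,000, base year 2025): ages 65–105 with
  exponentially thinning weights (rate 0.06/year of age, a realistic old-age
  pyramid); proportion female 0.52 at 65 rising 0.004/year (capped 0.72);
  education (low/medium/high, coded 0/1/2 with medium the regression
  reference) assigned from birth-cohort bands whose high-education share
  rises from 10% (born before 1930) to 23% (born 1960+).
* **Survey** (default n = 20,000): the *eligibility* logit
  P(hours > 65) and the *severity* logit P(hours ≥ 120 | > 65) are exact
  by construction — a Bernoulli draw from the logistic of the generating
  coefficients decides the band, then hours are placed uniformly inside
  open level intervals, so threshold ties cannot occur. Default
  coefficients (on x = (age − 85)/10): eligibility −1.7 + 0.9x + 0.12x²,
  +0.35 female, +0.45 low / −0.35 high education, with small first-order
  age interactions; severity −0.5 + 0.35x + 0.05x², +0.15 female,
  +0.35/−0.15 education. These give any-receipt prevalence of roughly 4%
  at 65 rising to ~40% in the mid-90s with a consistent education
  gradient. Above 180 h the three qualitative flags are drawn
  independently (0.50/0.35/0.15); dementia has probability
  min(0.01·e^{0.09(age−65)}, 0.5). The closed-form level distribution
  implied by all of this is available analytically and is the basis of the
  aggregate targets. Survey weights are ignored (the emulated pooling is
  unweighted).
* **Mortality**: Gompertz baseline, annual hazard a·e^{0.095(age−65)}
  with a = 0.013 (men) and 0.008 (women) at 65 — life expectancy at 65 of
  roughly 19/22 years — improving by 1.5%/year, with persistent education
  relative risks 1.25/1.0/0.8. Monthly probabilities are 1 − e^{−m/12}.
* **Entry**: 500 entrants/year growing 1%/year, high-education share
  drifting linearly from 23% to 35% by 2080 (non-decreasing, as
  educational expansion requires).
* **Targets**: benefit prevalence by age × sex × level is the
  education-weighted closed form above (a proper sub-distribution by
  construction); death targets by age × sex × year come from a
  deterministic projection of the *expected* population under the
  schedule, so the pipeline's mortality alignment recovers the schedule
  exactly — a designed-in consistency check.

## Estimation and alignment

Logits are fitted by maximum likelihood (statsmodels). The eligibility
design is a separate age polynomial (quadratic by default; the degree is
configurable, and degree 0 gives cell-saturated models) per sex ×
education cell — 18 free parameters; the severity design has age × sex and
age × education interactions but no three-way term (12 parameters).
Constant outcomes, constant cells (the finite-sample face of perfect
separation in interactive designs) and rank-deficient designs raise an
estimation error naming the offending cell. Average marginal predictions
set education to each group for the whole sample and average the predicted
probabilities; contrasts carry delta-method standard errors (validated
against a nonparametric bootstrap in the tests).

Alignment solves Σₑ wₑ·logistic(ηₑ + δ) = target per cell by bracketed
Brent root finding (the function is strictly increasing, so the root is
unique; tolerance 1e−12, with ±∞ sentinels for targets of 0 or 1). The
aligned level model is built per age × sex cell as: (1) eligibility-equation
education odds aligned to total any-receipt prevalence; (2)
severity-equation odds aligned to the levels-3–7 band, weighted by
per-education any-receipt; (3) within each band, every level carries the
band's education gradient scaled by its share of the band target. The
education-weighted aggregate therefore reproduces the statistics *exactly*
(machine precision), per-person level probabilities sum to the
any-receipt probability (< 1 structurally), and both fitted odds-ratio
structures persist. Alignment is cell-wise per single year of age, with no
smoothing across ages. Infeasible statistics (levels summing above 1, or
inconsistent weights) raise validation errors rather than being
renormalised silently.

Mortality alignment fits one hazard multiplier per year × age × sex by a
short fixed-point sweep inside a monthly deterministic projection (deaths
at age a depend on hazards at a − 1 earlier in the same calendar year, so
a closed form does not exist; convergence is to 1e−10 relative in a few
iterations). Education relative risks multiply the aligned baseline
unchanged. Targets exceeding the population at risk raise an error.

## Simulation engine

Monthly step order: (1) January entries at exactly age 65; (2) level
imputation for everyone alive at month start — so decedents receive the
payout of their death month — using lookup age
⌊65 + factor·(age − 65)⌋ clipped to 105, with education ignored when
differentials are off; (3) payout accrual in integer cents; (4) mortality
draws (S3 freezes the base-year hazard schedule); (5) ageing by one month.
The care-age factor applies to the full level-distribution lookup, i.e.
slower ageing slows both uptake and severity. Mortality does not depend on
the care level. Three named RNG substreams (mortality, care, entry) are
spawned from one seed, so scenarios under the same seed share common
random numbers wherever their population paths coincide — S0/S1/S2 have
identical death histories, which removes most between-scenario Monte-Carlo
variance from contrasts.

A deterministic companion projection propagates expected counts per
(age-month, sex, education) cell through the identical step order. Because
all engine draws are independent Bernoulli/multinomial events, this is the
exact expectation of every reported aggregate and serves as the
independent oracle for the Monte-Carlo engine in the tests.

## Accounting

Expenditure is recipients-per-level-month × monthly rate, in integer
cents, so the identity "sum of yearly totals = sum of individual
cumulative payouts" is asserted to the cent, and doubling the rate table
exactly doubles every monetary output. Annual prevalence cross-sections
are taken in December (no reference month is canonical; December makes
the final simulated year complete). Lifetime costs are undiscounted
constant-price sums for the cohort aged 65–75 at the start; members still
alive at the horizon are reported as censored with their stratum share,
never imputed. Empty strata are missing, not zero.

## Problem sizes in the tests

The statistical tests run at the estimation study conditions (survey
n = 20,000; 100 replications for coverage) and exercise the engine at
10,000 individuals over 2025–2080 for oracle equivalence; the
scenario-ordering and collapse-equivalence comparisons use 50 seeds at
2,000 individuals (the ordering and reversal are distributional properties
that do not require the larger population, and 50 × 4 full-horizon runs
stay comfortably fast at this size). All Monte-Carlo tests are seeded and
hence deterministic.

## What passing tests do and do not show

The generators reproduce the *structure* the method assumes: logistic
age/sex/education gradients that are exactly within the fitted model
family, independent hour placement inside bands, flags only above 180 h,
mortality with proportional improvement and persistent relative risks.
Real microdata would violate several of these (measurement error in
assessed hours, survey weighting, non-logistic age profiles, hazard
improvements varying by age and cohort, mortality selection on care
status), so green tests certify the pipeline's internal correctness —
estimation recovers its generating process, alignment is exact,
Monte-Carlo matches its expectation, scenario logic collapses and orders
as designed — not the accuracy of any national projection. In particular
the scenario ordering (S3 < S2 < S0 < S1 in final-year expenditure, and
the lifetime-cost gradient reversal between S0 and S1) is checked as an
ordinal property; absolute levels depend on the synthetic defaults.

## Known limitations

No fertility/migration feedback (entry cohorts are exogenous); no
in-kind services, informal-care supply or institutionalisation pathways;
no inflation indexation or discounting; mortality independent of care
level; the severity equation's education odds apply uniformly within a
band rather than per level (per-level statistics are still matched
exactly); cross-sectional imputation cannot describe the within-person
distribution of lifetime care (only stratum means are meaningful).
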