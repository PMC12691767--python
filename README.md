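# ltcsim

Dynamic microsimulation of demand for Austria's long-term-care allowance
(*Pflegegeld*) in an ageing population.

The allowance is a universal, needs-tested (not means-tested) cash benefit
paid in seven levels scaled to assessed monthly care hours: level 1 starts
above 65 h/month at EUR 200.80, level 7 pays EUR 2156.60 for more than
180 h when no purposeful movements of the four extremities are possible.
Dementia adds an automatic 40 h/month to the assessed need. `ltcsim`
projects how many people will receive which level — and what that costs,
in total and over individual lifetimes — as the population ages, longevity
improves, and educational expansion replaces older cohorts with
better-educated (and healthier) ones.

It is written for health economists and demographers who want a tested,
reproducible pipeline of the whole chain on synthetic data: estimating
care-need prevalence from survey-style microdata, calibrating it to
official benefit statistics, and simulating forward under morbidity and
mortality scenarios.

## The model

**Two-step prevalence estimation.** On a survey with assessed care hours,
a fully interactive logit (separate age polynomial per sex × education
cell) models *any receipt*, P(hours > 65 | age, sex, education). On the
recipient subsample a second logit with age × sex and age × education
interactions models the *severity band*, P(hours ≥ 120), which separates
levels 1–2 from levels 3–7.

**Alignment.** Official statistics give prevalence by single year of age,
sex and level, but not by education. Per age × sex cell, an additive shift
δ on the log-odds scale is solved (monotone root finding) so that the
education-weighted prevalence

&nbsp;&nbsp;&nbsp;&nbsp;Σₑ wₑ · logistic(ηₑ + δ) = target

matches the statistics exactly while the education odds ratios from the
fitted equations persist. The same logic aligns mortality: baseline
hazards are rescaled so expected deaths match aggregate targets by age,
sex and year, with education relative risks (default 1.25 / 1.0 / 0.8)
unchanged.

**Simulation.** A 65+ population evolves in monthly steps: January entry
cohorts at age 65 (with educational expansion), mortality draws from the
aligned hazards, and *cross-sectional imputation* of the allowance level —
each month every survivor draws a fresh level from P(level | age, sex,
education), with no longitudinal persistence by design. Four scenarios:

| scenario | meaning |
|---|---|
| S0 | baseline: mortality improvement + educational expansion |
| S1 | education differentials in prevalence switched off |
| S2 | slower ageing: care needs follow "care age" 65 + 0.8·(age − 65) |
| S3 | mortality frozen at the base year (no longevity gains) |

Accounting turns the monthly panel into annual expenditure by level (exact
integer-cent arithmetic), December prevalence cross-sections, and mean
lifetime allowance costs by sex × education for the starting 65–75 cohort.

## Worked example

`examples/03_run_scenarios.py` builds the full chain at the default sizes
(survey n = 20,000; population n = 10,000; horizon 2080) and prints:

```
scenario       2025 EUR       2080 EUR   growth
      S0     10,795,230     21,725,689    +101%
      S1     10,857,360     26,274,391    +142%
      S2      7,526,627     14,977,198     +99%
      S3     10,795,230     12,615,603     +17%
```

Final-year expenditure is ordered S3 < S2 < S0 < S1: most of the growth
comes from longevity gains (S0 vs S3), educational expansion dampens it
(S0 vs S1), and compression of morbidity (S2) lowers the level throughout.
The same script prints lifetime costs: under S0 they *fall* with education
(e.g. EUR 36,427 for low- vs 26,836 for high-educated women — a
pro-lower-education gradient), while under S1 the gradient reverses
(28,794 vs 43,387), because more educated people live longer and no longer
need less care per year once the differentials are switched off. These
figures are Monte-Carlo outputs on synthetic data; their qualitative
ordering, not their absolute size, is the result.

`examples/01_assessment_rules.py` demonstrates the rules engine,
`examples/02_estimate_and_align.py` the estimation/alignment round trip.
The pipeline is also scriptable from a shell:

```sh
ltcsim all --config examples/config.yaml --seed 1 --out run1
```

which writes every intermediate (population, survey, targets, fitted
coefficients, aligned model, per-scenario panels), the three reports per
scenario, and a manifest with the config hash and per-stream seeds;
rerunning with the same config and seed reproduces every file byte for
byte.

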