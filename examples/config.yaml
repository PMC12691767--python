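# Complete annotated configuration for the ltcsim pipeline.
# Any key omitted here falls back to the package default shown.
# Seeds are NOT configured in this file: every stage's stream seed is
# derived from the --seed passed on the command line (or to run_pipeline),
# so one integer reproduces the whole run.

population:
  # size of the synthetic 65+ starting population
  n_individuals: 10000
  # simulation starts in January of this year
  base_year: 2025
  # closed age range at the start; 105 is an open interval (105+ pooled)
  age_range: [65, 105]
  # proportion female; null selects the default age ramp
  # (0.52 at 65 rising by 0.004 per year of age, capped at 0.72)
  sex_share: null
  # "decline" thins the age pyramid exponentially (realistic); "uniform"
  # gives equal weight to every age in the range
  age_weights: decline

survey:
  # respondents in the synthetic care-need survey
  n_respondents: 20000
  # log-odds of assessed hours > 65 (any receipt); x = (age - 85) / 10
  eligibility_coefficients:
    intercept: -1.7
    x: 0.9
    x2: 0.12
    female: 0.35
    edu_low: 0.45        # low education needs care more often ...
    edu_high: -0.35      # ... high education less often
    "female:x": 0.10
    "edu_low:x": 0.05
    "edu_high:x": -0.05
  # log-odds of hours >= 120 (levels 3-7) given any receipt
  severity_coefficients:
    intercept: -0.5
    x: 0.35
    x2: 0.05
    female: 0.15
    edu_low: 0.35
    edu_high: -0.15
    "female:x": 0.05
    "edu_low:x": 0.05
    "edu_high:x": -0.05
  # split of the sub-120h band into levels 1 and 2
  level_split_low: [0.55, 0.45]
  # split of the 120h+ band into the (120,160), (160,180) and 180+ intervals
  level_split_high: [0.50, 0.20, 0.30]
  # probability of each qualitative criterion given hours > 180
  flag_probs:
    extraordinary_care: 0.50
    uncoordinated_day_night: 0.35
    no_purposeful_movements: 0.15
  # P(dementia | age) = min(base * exp(growth * (age - 65)), cap)
  dementia_base: 0.01
  dementia_growth: 0.09
  dementia_cap: 0.5

mortality:
  # Gompertz baseline: annual hazard rate_at_65 * exp(log_slope*(age-65)),
  # [male, female], medium education, base year
  rate_at_65: [0.013, 0.008]
  log_slope: 0.095
  # proportional hazard decline per calendar year (1.5% improvement)
  annual_improvement: 0.985
  # persistent relative risks [low, medium, high] education
  education_rr: [1.25, 1.0, 0.8]

entry:
  # 65-year-olds entering each January, growing at `growth` per year
  base_size: 500
  growth: 0.01
  # education composition drifts linearly between these endpoints
  # (educational expansion: the high-education share rises)
  start_composition: [0.28, 0.49, 0.23]
  end_composition: [0.15, 0.50, 0.35]
  female_share: 0.52

simulation:
  # last simulated calendar year (December cross-section reported)
  horizon: 2080
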