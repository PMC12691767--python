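"""Seeded generators for every input the projection pipeline consumes.

The real analysis would start from census microdata (age/sex/education of
the 65+ population), a survey with assessed monthly care-need hours, official
mortality and cohort projections, and benefit-prevalence statistics by single
year of age, sex and allowance level. This module emulates all four with the
statistical structure the estimation and simulation steps assume: logistic
age/sex/education gradients in care need, Gompertz mortality with a
proportional annual improvement and persistent education relative risks, and
educational expansion across entry cohorts.

Every generator is a pure function of its configuration, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import assessment
from .assessment import QUALITATIVE_FLAGS
from .design import natural_linear_predictor
from .prevalence import AGE_CAP, AGES, N_AGES, PrevalenceTable

__all__ = [
    "ConfigurationError",
    "PopulationConfig",
    "SurveyConfig",
    "MortalitySchedule",
    "EntrySchedule",
    "generate_population",
    "generate_survey",
    "generate_targets",
    "closed_form_level_probs",
    "education_weights",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


def _check_shares(shares, what: str) -> np.ndarray:
    s = np.asarray(shares, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ConfigurationError(f"{what}: shares must lie in [0, 1]")
    if abs(s.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"{what}: shares must sum to 1")
    return s


# Default education composition by birth cohort: later cohorts are more
# educated (educational expansion). Bands are (last birth year, shares).
DEFAULT_COHORT_EDUCATION = (
    (1929, (0.55, 0.35, 0.10)),
    (1939, (0.48, 0.40, 0.12)),
    (1949, (0.40, 0.44, 0.16)),
    (1959, (0.32, 0.48, 0.20)),
    (None, (0.28, 0.49, 0.23)),
)


@dataclass(frozen=True)
class PopulationConfig:
    """Starting 65+ population: marginals of age, sex and education.

    ``sex_share`` is either a scalar proportion female or ``None`` for the
    default age ramp (women outnumber men increasingly with age).
    ``age_weights`` is ``"decline"`` (realistic exponential thinning with
    age), ``"uniform"``, or an explicit weight array over the age grid.
    """

    n_individuals: int
    base_year: int = 2025
    age_range: tuple[int, int] = (65, 105)
    sex_share: float | None = None
    age_weights: str | np.ndarray = "decline"
    education_shares_by_cohort: tuple = DEFAULT_COHORT_EDUCATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigurationError("n_individuals must be positive")
        lo, hi = self.age_range
        if lo < 65 or hi < lo or hi > AGE_CAP:
            raise ConfigurationError(f"age_range must satisfy 65 <= lo <= hi <= {AGE_CAP}")
        if self.sex_share is not None and not 0 <= self.sex_share <= 1:
            raise ConfigurationError("sex_share must lie in [0, 1]")
        for _, shares in self.education_shares_by_cohort:
            _check_shares(shares, "education_shares_by_cohort")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_range[0], self.age_range[1] + 1)

    def age_distribution(self) -> np.ndarray:
        if isinstance(self.age_weights, str):
            if self.age_weights == "uniform":
                w = np.ones(len(self.ages))
            elif self.age_weights == "decline":
                w = np.exp(-0.06 * (self.ages - self.ages[0]))
            else:
                raise ConfigurationError(f"unknown age_weights {self.age_weights!r}")
        else:
            w = np.asarray(self.age_weights, dtype=float)
            if w.shape != self.ages.shape or np.any(w < 0) or w.sum() <= 0:
                raise ConfigurationError("age_weights array does not match the age grid")
        return w / w.sum()

    def female_share(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if self.sex_share is not None:
            return np.full(age.shape, float(self.sex_share))
        return np.minimum(0.52 + 0.004 * (age - 65), 0.72)

    def education_shares(self, birth_year) -> np.ndarray:
        """Shares (low, medium, high) for an array of birth years; (n, 3)."""
        birth_year = np.asarray(birth_year, dtype=int)
        out = np.empty(birth_year.shape + (3,))
        assigned = np.zeros(birth_year.shape, dtype=bool)
        for bound, shares in self.education_shares_by_cohort:
            mask = (~assigned) if bound is None else (~assigned) & (birth_year <= bound)
            out[mask] = np.asarray(shares, dtype=float)
            assigned |= mask
        return out


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw the starting population (id, age_months, sex, education)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    age_years = rng.choice(config.ages, size=n, p=config.age_distribution())
    age_months = age_years * 12 + rng.integers(0, 12, size=n)
    sex = (rng.random(n) < config.female_share(age_years)).astype(np.int8)
    shares = config.education_shares(config.base_year - age_years)
    u = rng.random(n)
    cum = np.cumsum(shares, axis=1)
    education = ((u[:, None] > cum[:, :2]).sum(axis=1)).astype(np.int8)
    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "age_months": age_months.astype(np.int32),
            "sex": sex,
            "education": education,
        }
    )


# --------------------------------------------------------------------------
# Survey of assessed care need
# --------------------------------------------------------------------------

DEFAULT_ELIGIBILITY_COEFS = {
    "intercept": -1.7,
    "x": 0.9,
    "x2": 0.12,
    "female": 0.35,
    "edu_low": 0.45,
    "edu_high": -0.35,
    "female:x": 0.10,
    "edu_low:x": 0.05,
    "edu_high:x": -0.05,
}

DEFAULT_SEVERITY_COEFS = {
    "intercept": -0.5,
    "x": 0.35,
    "x2": 0.05,
    "female": 0.15,
    "edu_low": 0.35,
    "edu_high": -0.15,
    "female:x": 0.05,
    "edu_low:x": 0.05,
    "edu_high:x": -0.05,
}

DEFAULT_FLAG_PROBS = {
    assessment.FLAG_EXTRAORDINARY: 0.50,
    assessment.FLAG_DAY_NIGHT: 0.35,
    assessment.FLAG_NO_MOVEMENT: 0.15,
}


@dataclass(frozen=True)
class SurveyConfig:
    """Generating process for the care-need survey.

    ``eligibility_coefficients`` give the log-odds of assessed hours above
    the level-1 threshold (65 h/month); ``severity_coefficients`` the
    log-odds of hours in the upper band (at least 120 h, levels 3-7) given
    eligibility. ``level_split_low`` partitions the lower band into the
    level-1 and level-2 hour intervals; ``level_split_high`` partitions the
    upper band into the intervals (120,160), (160,180) and above 180, where
    the qualitative flags decide between levels 4-7. Flags occur only above
    180 h.
    """

    n_respondents: int = 20_000
    age_range: tuple[int, int] = (65, 105)
    female_share: float = 0.5
    education_shares: tuple = (0.35, 0.40, 0.25)
    eligibility_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_ELIGIBILITY_COEFS))
    severity_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_SEVERITY_COEFS))
    level_split_low: tuple = (0.55, 0.45)
    level_split_high: tuple = (0.50, 0.20, 0.30)
    flag_probs: dict = field(default_factory=lambda: dict(DEFAULT_FLAG_PROBS))
    dementia_base: float = 0.01
    dementia_growth: float = 0.09
    dementia_cap: float = 0.5
    hours_cap: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ConfigurationError("n_respondents must be positive")
        _check_shares(self.education_shares, "education_shares")
        _check_shares(self.level_split_low, "level_split_low")
        _check_shares(self.level_split_high, "level_split_high")
        for flag, p in self.flag_probs.items():
            if flag not in QUALITATIVE_FLAGS:
                raise ConfigurationError(f"unknown flag {flag!r}")
            if not 0 <= p <= 1:
                raise ConfigurationError(f"flag_probs[{flag!r}] outside [0, 1]")
        if not 0 <= self.dementia_cap <= 1 or self.dementia_base < 0:
            raise ConfigurationError("dementia probability parameters out of range")
        if self.hours_cap <= 180:
            raise ConfigurationError("hours_cap must exceed 180")

    def eligibility_prob(self, age, sex, education) -> np.ndarray:
        return expit(natural_linear_predictor(self.eligibility_coefficients, age, sex, education))

    def severity_prob(self, age, sex, education) -> np.ndarray:
        return expit(natural_linear_predictor(self.severity_coefficients, age, sex, education))

    def dementia_prob(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return np.clip(self.dementia_base * np.exp(self.dementia_growth * (age - 65)), 0.0, self.dementia_cap)


def _open_uniform(rng: np.random.Generator, lo, hi) -> np.ndarray:
    """Uniform draws strictly inside (lo, hi) so band boundaries never tie."""
    u = rng.random(np.shape(lo) if np.ndim(lo) else None)
    u = np.where(u == 0.0, 0.5, u)
    return lo + (np.asarray(hi) - np.asarray(lo)) * u


def generate_survey(config: SurveyConfig) -> pd.DataFrame:
    """Draw survey records with assessed hours, dementia flag and flags.

    The eligibility logit governs P(hours > 65) exactly and the severity
    logit P(hours >= 120 | hours > 65) exactly; hours are then placed inside
    the level intervals according to the configured splits.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    lo_age, hi_age = config.age_range
    age = rng.integers(lo_age, hi_age + 1, size=n)
    sex = (rng.random(n) < config.female_share).astype(np.int8)
    cum_e = np.cumsum(config.education_shares)
    education = (rng.random(n)[:, None] > cum_e[:2]).sum(axis=1).astype(np.int8)

    eligible = rng.random(n) < config.eligibility_prob(age, sex, education)
    severe = np.zeros(n, dtype=bool)
    severe[eligible] = rng.random(eligible.sum()) < config.severity_prob(
        age[eligible], sex[eligible], education[eligible]
    )

    hours = np.empty(n)
    u_band = rng.random(n)
    # ineligible: below the 65 h threshold
    m = ~eligible
    hours[m] = _open_uniform(rng, np.zeros(m.sum()), 65.0)
    # lower band: (65, 95) for level 1, (95, 120) for level 2
    m = eligible & ~severe
    in_l2 = u_band[m] < config.level_split_low[1]
    lo = np.where(in_l2, 95.0, 65.0)
    hi = np.where(in_l2, 120.0, 95.0)
    hours[m] = _open_uniform(rng, lo, hi)
    # upper band: (120, 160), (160, 180), (180, cap)
    m = eligible & severe
    s3, s4, _ = config.level_split_high
    band = (u_band[m] > s3).astype(int) + (u_band[m] > s3 + s4).astype(int)
    lo = np.choose(band, [120.0, 160.0, 180.0])
    hi = np.choose(band, [160.0, 180.0, config.hours_cap])
    hours[m] = _open_uniform(rng, lo, hi)

    flags = np.zeros((n, len(QUALITATIVE_FLAGS)), dtype=bool)
    over180 = hours > 180.0
    for j, flag in enumerate(QUALITATIVE_FLAGS):
        p = config.flag_probs.get(flag, 0.0)
        flags[over180, j] = rng.random(over180.sum()) < p

    dementia = rng.random(n) < config.dementia_prob(age)
    base_hours = np.maximum(hours - assessment.DEMENTIA_PREMIUM_HOURS * dementia, 0.0)
    level = assessment.classify_levels(hours, flags)

    df = pd.DataFrame(
        {
            "age": age.astype(np.int16),
            "sex": sex,
            "education": education,
            "assessed_hours": hours,
            "base_hours": base_hours,
            "dementia": dementia,
            "level": level,
        }
    )
    for j, flag in enumerate(QUALITATIVE_FLAGS):
        df[flag] = flags[:, j]
    return df


def closed_form_level_probs(config: SurveyConfig, age, sex, education) -> np.ndarray:
    """Exact P(level 0..7 | age, sex, education) implied by the generator.

    Levels 5-7 resolve the independent flag draws by highest-satisfied
    criterion: P(7) = f7, P(6) = (1-f7) f6, P(5) = (1-f7)(1-f6) f5, and the
    remainder of the above-180 mass stays at level 4.
    """
    p_e = config.eligibility_prob(age, sex, education)
    p_s = config.severity_prob(age, sex, education)
    f5 = config.flag_probs.get(assessment.FLAG_EXTRAORDINARY, 0.0)
    f6 = config.flag_probs.get(assessment.FLAG_DAY_NIGHT, 0.0)
    f7 = config.flag_probs.get(assessment.FLAG_NO_MOVEMENT, 0.0)
    p7 = f7
    p6 = (1 - f7) * f6
    p5 = (1 - f7) * (1 - f6) * f5
    p4_extra = (1 - f7) * (1 - f6) * (1 - f5)
    sl1, sl2 = config.level_split_low
    s3, s4, s180 = config.level_split_high
    low = p_e * (1 - p_s)
    high = p_e * p_s
    out = np.stack(
        [
            1 - p_e,
            low * sl1,
            low * sl2,
            high * s3,
            high * (s4 + s180 * p4_extra),
            high * s180 * p5,
            high * s180 * p6,
            high * s180 * p7,
        ],
        axis=-1,
    )
    return out


# --------------------------------------------------------------------------
# Mortality and cohort entry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MortalitySchedule:
    """Base-year monthly death probabilities with improvement and education
    relative risks.

    ``monthly_q0`` is indexed by age 65..105 (rows) and sex (columns, male
    then female) and applies to the reference (medium) education group in the
    base year. Hazards decline by the factor ``annual_improvement`` per
    calendar year; education relative risks multiply the hazard and persist
    over time.
    """

    monthly_q0: np.ndarray
    annual_improvement: float | np.ndarray = 0.985
    education_rr: tuple = (1.25, 1.0, 0.8)

    def __post_init__(self) -> None:
        q = np.asarray(self.monthly_q0, dtype=float)
        if q.shape != (N_AGES, 2):
            raise ConfigurationError(f"monthly_q0 must have shape {(N_AGES, 2)}")
        if np.any(q <= 0) or np.any(q >= 1):
            raise ConfigurationError("monthly hazards must lie in (0, 1)")
        imp = np.asarray(self.annual_improvement, dtype=float)
        if np.any(imp <= 0) or np.any(imp > 1):
            raise ConfigurationError("annual_improvement must lie in (0, 1]")
        if np.any(np.asarray(self.education_rr) <= 0):
            raise ConfigurationError("education relative risks must be positive")
        object.__setattr__(self, "monthly_q0", q)

    @classmethod
    def gompertz(
        cls,
        rate_at_65=(0.013, 0.008),
        log_slope: float = 0.095,
        annual_improvement: float = 0.985,
        education_rr: tuple = (1.25, 1.0, 0.8),
    ) -> "MortalitySchedule":
        """Gompertz baseline: annual hazard a_sex * exp(slope*(age-65))."""
        m_year = np.outer(np.exp(log_slope * (AGES - 65)), np.asarray(rate_at_65))
        q0 = 1.0 - np.exp(-m_year / 12.0)
        return cls(q0, annual_improvement, education_rr)

    def monthly_m0(self) -> np.ndarray:
        """Monthly hazard rate (continuous scale) by age and sex."""
        return -np.log1p(-self.monthly_q0)

    def hazard_array(self, base_year: int, n_years: int) -> np.ndarray:
        """Monthly death probabilities H[year, age, sex, education]."""
        imp = np.broadcast_to(np.asarray(self.annual_improvement, dtype=float), (N_AGES,))
        m0 = self.monthly_m0()  # (ages, 2)
        years = np.arange(n_years)
        factor = imp[None, :, None] ** years[:, None, None]  # (years, ages, 1)
        m = m0[None, :, :] * factor  # (years, ages, 2)
        rr = np.asarray(self.education_rr, dtype=float)
        return 1.0 - np.exp(-m[..., None] * rr[None, None, None, :])


@dataclass(frozen=True)
class EntrySchedule:
    """Cohorts entering the simulation at age 65 each January."""

    years: np.ndarray
    cohort_size: np.ndarray
    education_composition: np.ndarray
    female_share: float = 0.52

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        size = np.asarray(self.cohort_size, dtype=int)
        comp = np.asarray(self.education_composition, dtype=float)
        if size.shape != years.shape or comp.shape != (len(years), 3):
            raise ConfigurationError("entry schedule arrays are inconsistent")
        if np.any(size < 0):
            raise ConfigurationError("cohort sizes must be non-negative")
        for row in comp:
            _check_shares(row, "education_composition")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "cohort_size", size)
        object.__setattr__(self, "education_composition", comp)

    @classmethod
    def expansion(
        cls,
        start_year: int,
        end_year: int,
        base_size: int = 500,
        growth: float = 0.01,
        start_composition=(0.28, 0.49, 0.23),
        end_composition=(0.15, 0.50, 0.35),
        female_share: float = 0.52,
    ) -> "EntrySchedule":
        """Growing cohorts with a linearly expanding high-education share."""
        years = np.arange(start_year, end_year + 1)
        size = np.round(base_size * (1 + growth) ** (years - start_year)).astype(int)
        t = (years - start_year) / max(1, end_year - start_year)
        comp = np.outer(1 - t, start_composition) + np.outer(t, end_composition)
        return cls(years, size, comp, female_share)

    def for_year(self, year: int):
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            return 0, np.array([0.0, 1.0, 0.0])
        return int(self.cohort_size[idx]), self.education_composition[idx]


# --------------------------------------------------------------------------
# Aggregate targets
# --------------------------------------------------------------------------


def education_weights(config: PopulationConfig) -> np.ndarray:
    """Base-year education composition by age and sex, shape (n_ages, 2, 3).

    The generator's education shares depend on birth cohort only, so both
    sexes carry the same composition at a given age.
    """
    shares = config.education_shares(config.base_year - AGES)  # (n_ages, 3)
    return np.broadcast_to(shares[:, None, :], (N_AGES, 2, 3)).copy()


def generate_targets(
    pop: PopulationConfig,
    mort: MortalitySchedule,
    entry: EntrySchedule,
    survey_truth: SurveyConfig,
    horizon: int | None = None,
):
    """Official-style aggregate targets implied by the generating process.

    Returns ``(PrevalenceTable, deaths)`` where the prevalence table is the
    education-weighted closed-form level distribution (by single year of age
    and sex) and ``deaths`` is a DataFrame of expected deaths by age, sex and
    calendar year from a deterministic projection of the expected population
    under the mortality schedule and entry cohorts.
    """
    from . import projection

    if pop.age_range[1] > AGE_CAP or survey_truth.age_range[1] > AGE_CAP:
        raise ConfigurationError("age ranges exceed the pooled 105+ cap")
    if survey_truth.age_range[0] > pop.age_range[0]:
        raise ConfigurationError(
            "survey age range does not cover the population age range"
        )
    horizon = pop.base_year if horizon is None else horizon

    w = education_weights(pop)  # (ages, 2, 3)
    probs = np.zeros((N_AGES, 2, 7))
    for s in (0, 1):
        for e in (0, 1, 2):
            cell = closed_form_level_probs(survey_truth, AGES, np.full(N_AGES, s), np.full(N_AGES, e))
            probs[:, s, :] += w[:, s, e, None] * cell[:, 1:]
    table = PrevalenceTable(probs)

    c0 = projection.expected_initial_counts(pop)
    n_years = horizon - pop.base_year + 1
    H = mort.hazard_array(pop.base_year, n_years)
    res = projection.project(c0, H, entry, pop.base_year, horizon)
    deaths = projection.deaths_to_frame(res["deaths"], pop.base_year)
    return table, deaths
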