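"""Monthly stochastic population engine for the 65+ care-allowance module.

Each month, in order: January cohort entry at age 65; cross-sectional
imputation of the allowance level for everyone alive at month start (an
independent draw from the aligned prevalence model — no longitudinal
persistence by design); payout accrual, so decedents still receive the
month in which they die; mortality draws from aligned hazards (education
relative risks persist); ageing by one month.

Scenarios switch three things: education differentials in the prevalence
lookup, the care-age factor (a person ages ``factor`` care years per
calendar year past 65, so lookups use a younger age), and whether mortality
improves over calendar time or stays frozen at the base year.

Random numbers come from three named substreams (mortality, care, entry)
spawned from one seed, so scenario comparisons under the same seed share
common random numbers wherever their population paths coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assessment import DEFAULT_RULES, AssessmentRuleTable
from .panel import MonthlyPanel
from .prevalence import AGE_CAP, AGE_MIN, AGES, N_AGES, AlignedPrevalenceModel
from .projection import (  # re-exported: alignment lives with the projection
    InfeasibleTargetError,
    align_mortality,
    solve_baseline_hazard,
)

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "care_age",
    "SimulationState",
    "step_month",
    "run_scenario",
    "align_mortality",
    "solve_baseline_hazard",
    "InfeasibleTargetError",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario switches.

    ``care_age_factor`` = 1 leaves ages untouched; 0.8 means four care
    years per five calendar years. ``mortality_mode`` is ``"projected"``
    (hazards improve over calendar time) or ``"constant_base_year"``.
    """

    label: str
    education_differentials: bool = True
    care_age_factor: float = 1.0
    mortality_mode: str = "projected"

    def __post_init__(self) -> None:
        if not 0 < self.care_age_factor <= 1:
            raise ValueError("care_age_factor must lie in (0, 1]")
        if self.mortality_mode not in ("projected", "constant_base_year"):
            raise ValueError(f"unknown mortality_mode {self.mortality_mode!r}")


#: The four named scenarios: baseline, no education differentials,
#: slower ageing, constant mortality.
SCENARIOS = {
    "S0": ScenarioConfig("S0"),
    "S1": ScenarioConfig("S1", education_differentials=False),
    "S2": ScenarioConfig("S2", care_age_factor=0.8),
    "S3": ScenarioConfig("S3", mortality_mode="constant_base_year"),
}


def care_age(chronological_age, factor: float):
    """Care age: 65 + factor * (age - 65); identity when factor is 1.

    Under slower ageing (factor 0.8) a 70-year-old has care age 69 and a
    90-year-old is "the new 85".
    """
    age = np.asarray(chronological_age, dtype=float)
    if np.any(age < 65):
        raise ValueError("care_age is defined for ages 65 and older")
    out = 65.0 + factor * (age - 65.0)
    return float(out) if np.isscalar(chronological_age) else out


@dataclass
class SimulationState:
    """Mutable state of one run: individual arrays, clock, RNG streams,
    accumulated tallies and the event log."""

    base_year: int
    horizon: int
    year: int
    month: int  # 0..11
    id: np.ndarray
    sex: np.ndarray
    education: np.ndarray
    age_months: np.ndarray
    alive: np.ndarray
    level: np.ndarray
    cum_cents: np.ndarray
    age_start_months: np.ndarray
    entry_year: np.ndarray
    death_year: np.ndarray
    death_month: np.ndarray
    rng_mortality: np.random.Generator
    rng_care: np.random.Generator
    rng_entry: np.random.Generator
    counts: np.ndarray  # (n_years, 12, 8)
    december: np.ndarray  # (n_years, n_ages, 2, 3, 8)
    deaths: np.ndarray  # (n_years, n_ages, 2)
    events: list = field(default_factory=list)

    @classmethod
    def from_population(
        cls, population: pd.DataFrame, base_year: int, horizon: int, seed: int
    ) -> "SimulationState":
        if horizon < base_year:
            raise ValueError("horizon must not precede the base year")
        n = len(population)
        n_years = horizon - base_year + 1
        ss = np.random.SeedSequence(seed)
        mort_ss, care_ss, entry_ss = ss.spawn(3)
        return cls(
            base_year=base_year,
            horizon=horizon,
            year=base_year,
            month=0,
            id=population["id"].to_numpy(np.int64).copy(),
            sex=population["sex"].to_numpy(np.int8).copy(),
            education=population["education"].to_numpy(np.int8).copy(),
            age_months=population["age_months"].to_numpy(np.int32).copy(),
            alive=np.ones(n, dtype=bool),
            level=np.zeros(n, dtype=np.int8),
            cum_cents=np.zeros(n, dtype=np.int64),
            age_start_months=population["age_months"].to_numpy(np.int32).copy(),
            entry_year=np.full(n, base_year, dtype=np.int32),
            death_year=np.full(n, -1, dtype=np.int32),
            death_month=np.full(n, -1, dtype=np.int32),
            rng_mortality=np.random.default_rng(mort_ss),
            rng_care=np.random.default_rng(care_ss),
            rng_entry=np.random.default_rng(entry_ss),
            counts=np.zeros((n_years, 12, 8), dtype=np.int64),
            december=np.zeros((n_years, N_AGES, 2, 3, 8), dtype=np.int64),
            deaths=np.zeros((n_years, N_AGES, 2), dtype=np.int64),
        )

    def _append(self, sex, education) -> None:
        k = len(sex)
        next_id = self.id.max() + 1 if len(self.id) else 0
        self.id = np.concatenate([self.id, next_id + np.arange(k)])
        self.sex = np.concatenate([self.sex, sex.astype(np.int8)])
        self.education = np.concatenate([self.education, education.astype(np.int8)])
        self.age_months = np.concatenate(
            [self.age_months, np.full(k, AGE_MIN * 12, dtype=np.int32)]
        )
        self.alive = np.concatenate([self.alive, np.ones(k, dtype=bool)])
        self.level = np.concatenate([self.level, np.zeros(k, dtype=np.int8)])
        self.cum_cents = np.concatenate([self.cum_cents, np.zeros(k, dtype=np.int64)])
        self.age_start_months = np.concatenate(
            [self.age_start_months, np.full(k, AGE_MIN * 12, dtype=np.int32)]
        )
        self.entry_year = np.concatenate(
            [self.entry_year, np.full(k, self.year, dtype=np.int32)]
        )
        self.death_year = np.concatenate([self.death_year, np.full(k, -1, dtype=np.int32)])
        self.death_month = np.concatenate([self.death_month, np.full(k, -1, dtype=np.int32)])


def step_month(
    state: SimulationState,
    scenario: ScenarioConfig,
    hazards: np.ndarray,
    entry,
    prevalence_model: AlignedPrevalenceModel,
    rules: AssessmentRuleTable = DEFAULT_RULES,
) -> SimulationState:
    """Advance the state by one month (entry, care imputation, payout,
    mortality, ageing). ``hazards`` is H[year, age, sex, education] of
    aligned monthly death probabilities starting at the base year."""
    yi = state.year - state.base_year
    n_entries = 0
    if state.month == 0 and state.year > state.base_year:
        size, comp = entry.for_year(state.year)
        if size:
            sex = (state.rng_entry.random(size) < entry.female_share).astype(np.int8)
            cum = np.cumsum(comp)
            edu = (state.rng_entry.random(size)[:, None] > cum[:2]).sum(axis=1)
            state._append(sex, edu)
            n_entries = size

    idx = np.flatnonzero(state.alive)
    alive_start = len(idx)
    ages_y = state.age_months[idx] // 12
    ai_cap = np.minimum(ages_y, AGE_CAP) - AGE_MIN

    # cross-sectional care imputation at the (floored, capped) care age
    la = np.clip(
        np.floor(65.0 + scenario.care_age_factor * (ages_y - 65.0)).astype(int),
        AGE_MIN,
        AGE_CAP,
    ) - AGE_MIN
    cum = prevalence_model.cumulative(scenario.education_differentials)
    rows = cum[la, state.sex[idx], state.education[idx]]  # (n, 8)
    u = state.rng_care.random(alive_start)
    lev = (u[:, None] >= rows[:, :7]).sum(axis=1).astype(np.int8)
    state.level[:] = 0
    state.level[idx] = lev
    state.cum_cents[idx] += rules.payout_cents_vector()[lev]
    state.counts[yi, state.month] += np.bincount(lev, minlength=8)
    if state.month == 11:
        np.add.at(
            state.december[yi],
            (ai_cap, state.sex[idx], state.education[idx], lev),
            1,
        )

    # mortality: frozen at the base year under constant mortality
    h_yi = 0 if scenario.mortality_mode == "constant_base_year" else yi
    q = hazards[h_yi, ai_cap, state.sex[idx], state.education[idx]]
    die = state.rng_mortality.random(alive_start) < q
    died = idx[die]
    np.add.at(state.deaths[yi], (ai_cap[die], state.sex[idx][die]), 1)
    state.alive[died] = False
    state.level[died] = 0
    state.death_year[died] = state.year
    state.death_month[died] = state.month + 1

    state.events.append(
        (state.year, state.month + 1, alive_start, n_entries, len(died),
         alive_start - len(died))
    )
    state.age_months[state.alive] += 1
    state.month += 1
    if state.month == 12:
        state.month = 0
        state.year += 1
    return state


def run_scenario(
    population: pd.DataFrame,
    scenario: ScenarioConfig,
    hazards: np.ndarray,
    entry,
    prevalence_model: AlignedPrevalenceModel,
    horizon: int,
    base_year: int,
    seed: int,
    rules: AssessmentRuleTable = DEFAULT_RULES,
) -> MonthlyPanel:
    """Run one scenario from January of ``base_year`` to December of
    ``horizon`` and return the monthly panel. Deterministic given the seed."""
    n_years = horizon - base_year + 1
    if hazards.shape[0] < n_years:
        raise ValueError("hazard array does not cover the simulation horizon")
    state = SimulationState.from_population(population, base_year, horizon, seed)
    for _ in range(n_years * 12):
        step_month(state, scenario, hazards, entry, prevalence_model, rules)

    years = base_year + np.arange(n_years)
    yy, mm, ll = np.meshgrid(years, np.arange(1, 13), np.arange(8), indexing="ij")
    counts = pd.DataFrame(
        {"year": yy.ravel(), "month": mm.ravel(), "level": ll.ravel(),
         "n": state.counts.ravel()}
    )
    nz = np.argwhere(state.december > 0)
    december = pd.DataFrame(
        {
            "year": years[nz[:, 0]],
            "age": AGES[nz[:, 1]],
            "sex": nz[:, 2],
            "education": nz[:, 3],
            "level": nz[:, 4],
            "n": state.december[tuple(nz.T)],
        }
    )
    individuals = pd.DataFrame(
        {
            "id": state.id,
            "sex": state.sex,
            "education": state.education,
            "age_start_months": state.age_start_months,
            "entry_year": state.entry_year,
            "death_year": state.death_year,
            "death_month": state.death_month,
            "cum_cents": state.cum_cents,
            "alive": state.alive,
        }
    )
    events = pd.DataFrame(
        state.events,
        columns=["year", "month", "alive_start", "entries", "deaths", "alive_end"],
    )
    return MonthlyPanel(
        base_year=base_year,
        horizon=horizon,
        scenario=scenario.label,
        seed=seed,
        counts=counts,
        december=december,
        individuals=individuals,
        events=events,
    )
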