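"""Shared fixtures: one session-scoped model chain at study-condition sizes
(survey n=20,000; population n=10,000; horizon 2080) reused across unit and
acceptance tests, plus a helper to assemble small panels by hand."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from ltcsim import engine, estimation, projection, synthetic
from ltcsim.panel import MonthlyPanel

BASE_YEAR = 2025
HORIZON = 2080


@pytest.fixture(scope="session")
def chain():
    """Full generate -> fit -> align -> mortality-align chain."""
    pop_cfg = synthetic.PopulationConfig(n_individuals=10_000, seed=11)
    svy_cfg = synthetic.SurveyConfig(n_respondents=20_000, seed=7)
    mort = synthetic.MortalitySchedule.gompertz()
    entry = synthetic.EntrySchedule.expansion(BASE_YEAR + 1, HORIZON)
    survey = synthetic.generate_survey(svy_cfg)
    elig = estimation.fit_logit(estimation.LogitSpec("eligibility"), survey)
    sev = estimation.fit_logit(estimation.LogitSpec("severity"), survey)
    table, deaths_df = synthetic.generate_targets(pop_cfg, mort, entry, svy_cfg, HORIZON)
    weights = synthetic.education_weights(pop_cfg)
    model = estimation.build_prevalence_model(elig, sev, table, weights)
    c0 = projection.expected_initial_counts(pop_cfg)
    targets = projection.deaths_from_frame(deaths_df, BASE_YEAR, HORIZON - BASE_YEAR + 1)
    hazards = projection.align_mortality(mort, c0, entry, targets, BASE_YEAR)
    population = synthetic.generate_population(pop_cfg)
    return SimpleNamespace(
        pop_cfg=pop_cfg,
        svy_cfg=svy_cfg,
        mort=mort,
        entry=entry,
        survey=survey,
        elig=elig,
        sev=sev,
        table=table,
        deaths_df=deaths_df,
        weights=weights,
        model=model,
        c0=c0,
        death_targets=targets,
        hazards=hazards,
        population=population,
        base_year=BASE_YEAR,
        horizon=HORIZON,
    )


@pytest.fixture(scope="session")
def panel_s0(chain) -> MonthlyPanel:
    """One baseline run over the full horizon at the default size."""
    return engine.run_scenario(
        chain.population,
        engine.SCENARIOS["S0"],
        chain.hazards,
        chain.entry,
        chain.model,
        horizon=HORIZON,
        base_year=BASE_YEAR,
        seed=3,
    )


def make_panel(counts_rows, individuals_rows, december_rows=(), base_year=2025,
               horizon=2025, scenario="test", seed=0) -> MonthlyPanel:
    """Assemble a panel from explicit rows.

    counts_rows: (year, month, level, n); individuals_rows: dicts with the
    individuals-frame columns; december_rows: (year, age, sex, education,
    level, n).
    """
    counts = pd.DataFrame(counts_rows, columns=["year", "month", "level", "n"])
    defaults = {
        "id": 0, "sex": 0, "education": 1, "age_start_months": 70 * 12,
        "entry_year": base_year, "death_year": -1, "death_month": -1,
        "cum_cents": 0, "alive": True,
    }
    individuals = pd.DataFrame(
        [{**defaults, **row} for row in individuals_rows] or None,
        columns=list(defaults),
    )
    december = pd.DataFrame(
        list(december_rows), columns=["year", "age", "sex", "education", "level", "n"]
    )
    events = pd.DataFrame(columns=["year", "month", "alive_start", "entries",
                                   "deaths", "alive_end"])
    return MonthlyPanel(base_year, horizon, scenario, seed, counts, december,
                        individuals, events)


@pytest.fixture
def small_entry():
    """Entry schedule with no cohorts (empty years)."""
    return synthetic.EntrySchedule(
        years=np.array([], dtype=int),
        cohort_size=np.array([], dtype=int),
        education_composition=np.zeros((0, 3)),
    )


def uniform_level_model(level: int = 1, prob: float = 1.0):
    """Aligned model putting mass ``prob`` on one level everywhere."""
    from ltcsim.prevalence import AlignedPrevalenceModel, N_AGES

    probs = np.zeros((N_AGES, 2, 3, 8))
    probs[..., level] = prob
    probs[..., 0] = 1.0 - prob
    weights = np.full((N_AGES, 2, 3), 1 / 3)
    return AlignedPrevalenceModel(probs, weights)
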