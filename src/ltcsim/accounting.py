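"""Reports from a simulated panel: annual expenditure by allowance level,
lifetime allowance costs by sex and education, and prevalence cross-sections.

All monetary arithmetic is carried out in integer cents so that the
conservation identity — yearly expenditure summed over the horizon equals
the sum of individual cumulative payouts — holds to the cent, not merely to
floating-point tolerance. Amounts are reported in EUR at constant prices
(whatever fixed rate schedule was configured).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assessment import DEFAULT_RULES, AssessmentRuleTable
from .design import EDU_LABELS, SEX_LABELS
from .panel import MonthlyPanel

__all__ = [
    "ExpenditureReport",
    "annual_expenditure",
    "lifetime_costs",
    "prevalence_report",
]


@dataclass(frozen=True)
class ExpenditureReport:
    """Annual expenditure in EUR by year and level, plus yearly totals."""

    table: pd.DataFrame  # index year, columns level 1..7, values EUR
    totals: pd.Series  # index year, EUR

    def total(self, year: int) -> float:
        return float(self.totals.loc[year])


def annual_expenditure(
    panel: MonthlyPanel,
    rules: AssessmentRuleTable = DEFAULT_RULES,
    allow_partial: bool = False,
) -> ExpenditureReport:
    """Sum recipients-by-level over the months of each calendar year times
    the monthly rate. Raises on partial years unless explicitly allowed."""
    counts = panel.counts
    months_per_year = counts.groupby("year")["month"].nunique()
    if not allow_partial and (months_per_year != 12).any():
        bad = months_per_year[months_per_year != 12].index.tolist()
        raise ValueError(f"panel covers partial years {bad}; pass allow_partial=True")
    pay = rules.payout_cents_vector()
    cents = (
        counts.assign(cents=lambda d: d["n"].to_numpy() * pay[d["level"].to_numpy()])
        .groupby(["year", "level"])["cents"]
        .sum()
        .unstack("level", fill_value=0)
    )
    cents = cents.reindex(columns=range(0, rules.n_levels + 1), fill_value=0)
    eur = cents / 100.0
    totals = eur.sum(axis=1)
    return ExpenditureReport(table=eur.drop(columns=[0]), totals=totals)


def lifetime_costs(panel: MonthlyPanel, cohort: tuple = (65, 75)) -> pd.DataFrame:
    """Mean cumulative allowance per person over remaining life, by sex and
    education, for those aged within ``cohort`` at simulation start.

    Members still alive at the horizon are censored, not imputed; the
    censoring share is reported per stratum. Strata with no members are
    reported as missing (NaN), not zero.
    """
    lo, hi = cohort
    ind = panel.individuals
    start_age = ind["age_start_months"] // 12
    members = ind[
        (ind["entry_year"] == panel.base_year) & (start_age >= lo) & (start_age <= hi)
    ]
    rows = []
    for s in (0, 1):
        for e in (0, 1, 2):
            grp = members[(members["sex"] == s) & (members["education"] == e)]
            if len(grp) == 0:
                rows.append((SEX_LABELS[s], EDU_LABELS[e], 0, np.nan, np.nan))
                continue
            mean_eur = grp["cum_cents"].mean() / 100.0
            rows.append(
                (
                    SEX_LABELS[s],
                    EDU_LABELS[e],
                    len(grp),
                    mean_eur,
                    float(grp["alive"].mean()),
                )
            )
    return pd.DataFrame(
        rows, columns=["sex", "education", "n", "mean_lifetime_eur", "censored_share"]
    )


def prevalence_report(panel: MonthlyPanel, year: int) -> pd.DataFrame:
    """December cross-section: recipients by age, sex and level with
    population denominators."""
    if year not in set(panel.years()):
        raise ValueError(f"year {year} outside the simulated horizon")
    dec = panel.december[panel.december["year"] == year]
    pop = (
        dec.groupby(["age", "sex"])["n"].sum().rename("population").reset_index()
    )
    levels = (
        dec[dec["level"] > 0]
        .groupby(["age", "sex", "level"])["n"]
        .sum()
        .rename("recipients")
        .reset_index()
    )
    out = levels.merge(pop, on=["age", "sex"], how="right").fillna(
        {"level": 0, "recipients": 0}
    )
    out["level"] = out["level"].astype(int)
    out["recipients"] = out["recipients"].astype(int)
    return out.sort_values(["age", "sex", "level"]).reset_index(drop=True)
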