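"""Deterministic expected-population projection.

Propagates expected person counts per (age-in-months, sex, education) cell
through the same monthly dynamics as the stochastic engine: January cohort
entry, cross-sectional care imputation on the population alive at month
start, mortality, then ageing by one month. Because the engine's draws are
independent Bernoulli/multinomial events, this projection is the exact
expectation of every aggregate the engine reports, which makes it (a) the
generator of official-style death targets, (b) the machinery behind
mortality alignment, and (c) an independent oracle for Monte-Carlo runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .prevalence import AGE_CAP, AGE_MIN, AGES, N_AGES

__all__ = [
    "InfeasibleTargetError",
    "expected_initial_counts",
    "project",
    "deaths_to_frame",
    "align_mortality",
    "solve_baseline_hazard",
]

#: age-in-months grid: 65*12 .. (125*12 - 1), absorbing at the top
MONTH_MIN = AGE_MIN * 12
N_MONTH_CELLS = (125 - AGE_MIN) * 12

_AGE_YEARS = (MONTH_MIN + np.arange(N_MONTH_CELLS)) // 12
_AGE_IDX_CAPPED = np.minimum(_AGE_YEARS, AGE_CAP) - AGE_MIN


class InfeasibleTargetError(ValueError):
    """Aggregate target cannot be met by the population at risk."""


def expected_initial_counts(pop_config) -> np.ndarray:
    """Expected starting counts per (age-month, sex, education) cell."""
    c = np.zeros((N_MONTH_CELLS, 2, 3))
    p_age = pop_config.age_distribution()
    fshare = pop_config.female_share(pop_config.ages)
    shares = pop_config.education_shares(pop_config.base_year - pop_config.ages)
    for k, age in enumerate(pop_config.ages):
        base = pop_config.n_individuals * p_age[k] / 12.0
        lo = age * 12 - MONTH_MIN
        for off in range(12):
            c[lo + off, 0, :] = base * (1 - fshare[k]) * shares[k]
            c[lo + off, 1, :] = base * fshare[k] * shares[k]
    return c


def _care_lookup_index(factor: float) -> np.ndarray:
    """Prevalence-row index per age-month cell under the care-age map."""
    care = AGE_MIN + factor * (_AGE_YEARS - AGE_MIN)
    return (np.clip(np.floor(care).astype(int), AGE_MIN, AGE_CAP) - AGE_MIN)


def _entry_add(c: np.ndarray, entry, year: int) -> None:
    size, comp = entry.for_year(year)
    if size:
        c[0, 0, :] += size * (1 - entry.female_share) * comp
        c[0, 1, :] += size * entry.female_share * comp


def _age_one_month(c: np.ndarray) -> None:
    top = c[-1].copy()
    c[1:] = c[:-1]
    c[0] = 0.0
    c[-1] += top


def project(
    c0: np.ndarray,
    hazards: np.ndarray,
    entry,
    base_year: int,
    horizon: int,
    prevalence_model=None,
    care_age_factor: float = 1.0,
    education_differentials: bool = True,
    payout_cents=None,
    collect_december: bool = False,
) -> dict:
    """Propagate expected counts from January of ``base_year`` through
    December of ``horizon``.

    ``hazards`` is H[year, age, sex, education] of monthly death
    probabilities (already aligned/scenario-adjusted). With a prevalence
    model the expected recipients per level and (optionally) expected
    expenditure are accumulated exactly as the engine does: levels are
    imputed on everyone alive at month start, so decedents receive that
    month's payout.
    """
    c = np.asarray(c0, dtype=float).copy()
    if c.shape != (N_MONTH_CELLS, 2, 3):
        raise ValueError("initial counts must be on the month-cell grid")
    n_years = horizon - base_year + 1
    deaths = np.zeros((n_years, N_AGES, 2))
    level_exp = np.zeros((n_years, 8))
    expend = np.zeros((n_years, 8))
    december = np.zeros((n_years, N_AGES, 2, 3, 8)) if collect_december else None

    P = None
    if prevalence_model is not None:
        la = _care_lookup_index(care_age_factor)
        if education_differentials:
            P = prevalence_model.probs[la]  # (cells, 2, 3, 8)
        else:
            marg = prevalence_model.marginal().probs
            p0 = 1.0 - marg.sum(axis=2, keepdims=True)
            full = np.concatenate([p0, marg], axis=2)[la]  # (cells, 2, 8)
            P = np.broadcast_to(full[:, :, None, :], (N_MONTH_CELLS, 2, 3, 8))
    pay = None if payout_cents is None else np.asarray(payout_cents, dtype=float)

    for yi in range(n_years):
        year = base_year + yi
        Hy = hazards[yi][_AGE_IDX_CAPPED]  # (cells, 2, 3)
        for m in range(12):
            if m == 0:
                _entry_add(c, entry, year)
            if P is not None:
                lev = np.einsum("cse,csel->l", c, P)
                level_exp[yi] += lev
                if pay is not None:
                    expend[yi] += lev * pay
                if collect_december and m == 11:
                    np.add.at(december[yi], _AGE_IDX_CAPPED, c[..., None] * P)
            d = c * Hy
            np.add.at(deaths[yi], _AGE_IDX_CAPPED, d.sum(axis=2))
            c -= d
            _age_one_month(c)

    out = {
        "deaths": deaths,
        "level_person_months": level_exp,
        "expenditure_cents": expend,
        "final_counts": c,
    }
    if collect_december:
        out["december"] = december
    return out


def deaths_to_frame(deaths: np.ndarray, base_year: int) -> pd.DataFrame:
    n_years = deaths.shape[0]
    years, ages, sexes = np.meshgrid(
        base_year + np.arange(n_years), AGES, [0, 1], indexing="ij"
    )
    return pd.DataFrame(
        {
            "year": years.ravel(),
            "age": ages.ravel(),
            "sex": sexes.ravel(),
            "deaths": deaths.ravel(),
        }
    )


def deaths_from_frame(df: pd.DataFrame, base_year: int, n_years: int) -> np.ndarray:
    deaths = np.zeros((n_years, N_AGES, 2))
    yi = df["year"].to_numpy(int) - base_year
    ai = np.clip(df["age"].to_numpy(int), AGE_MIN, AGE_CAP) - AGE_MIN
    np.add.at(deaths, (yi, ai, df["sex"].to_numpy(int)), df["deaths"].to_numpy(float))
    return deaths


def solve_baseline_hazard(n_by_education, relative_risks, target_deaths) -> float:
    """Baseline hazard h such that expected deaths sum n_e * h * rr_e hit
    the target in a single period; relative risks between education groups
    are untouched."""
    n = np.asarray(n_by_education, dtype=float)
    rr = np.asarray(relative_risks, dtype=float)
    denom = float(np.dot(n, rr))
    if denom <= 0:
        raise InfeasibleTargetError("no population at risk")
    if target_deaths > n.sum():
        raise InfeasibleTargetError("target deaths exceed the cell population")
    return float(target_deaths) / denom


def align_mortality(
    schedule,
    c0: np.ndarray,
    entry,
    target_deaths: np.ndarray,
    base_year: int,
    max_iter: int = 30,
    tol: float = 1e-10,
) -> np.ndarray:
    """Adjust baseline hazards so expected deaths match annual targets.

    For each calendar year and age×sex cell a multiplier on the hazard rate
    is fitted by a fixed-point sweep (deaths at an age depend on hazards at
    the preceding age earlier in the same year, so a handful of sweeps are
    needed); education relative risks multiply the aligned baseline
    unchanged, which preserves the risk ratios between education groups.

    Returns adjusted monthly death probabilities H[year, age, sex, education].
    """
    n_years = target_deaths.shape[0]
    if target_deaths.shape != (n_years, N_AGES, 2):
        raise ValueError("targets must be on the (year, age, sex) grid")
    if np.any(target_deaths < 0):
        raise InfeasibleTargetError("negative death target")

    imp = np.broadcast_to(np.asarray(schedule.annual_improvement, dtype=float), (N_AGES,))
    m0 = schedule.monthly_m0()  # (ages, 2)
    rr = np.asarray(schedule.education_rr, dtype=float)

    H_adj = np.zeros((n_years, N_AGES, 2, 3))
    c = np.asarray(c0, dtype=float).copy()
    for yi in range(n_years):
        year = base_year + yi
        m_year = m0 * (imp[:, None] ** yi)  # (ages, 2)
        mult = np.ones((N_AGES, 2))
        target = target_deaths[yi]
        at_risk = c.sum() + entry.for_year(year)[0]
        if target.sum() > at_risk * (1 + 1e-9):
            raise InfeasibleTargetError(
                f"year {year}: targets exceed the population at risk"
            )
        for it in range(max_iter):
            m_cells = (m_year * mult)[_AGE_IDX_CAPPED] # (cells, 2)
            q = 1.0 - np.exp(-m_cells[..., None] * rr)  # (cells, 2, 3)
            cc = c.copy()
            achieved = np.zeros((N_AGES, 2))
            for m in range(12):
                if m == 0:
                    _entry_add(cc, entry, year)
                d = cc * q
                np.add.at(achieved, _AGE_IDX_CAPPED, d.sum(axis=2))
                cc -= d
                _age_one_month(cc)
            err = np.abs(achieved - target)
            populated = achieved > 1e-12
            if np.all(err[populated] <= tol * np.maximum(1.0, target[populated])) and np.all(
                target[~populated] <= 1e-9
            ):
                break
            ratio = np.ones_like(mult)
            ratio[populated] = target[populated] / achieved[populated]
            mult *= ratio
            if np.any(mult > 1e8):
                bad = np.argwhere(mult > 1e8)[0]
                raise InfeasibleTargetError(
                    f"year {year}, age {AGES[bad[0]]}, sex {bad[1]}: "
                    "target deaths exceed the cell population"
                )
        else:
            worst = np.unravel_index(np.argmax(err), err.shape)
            raise InfeasibleTargetError(
                f"year {year}: alignment did not converge (worst cell age "
                f"{AGES[worst[0]]}, sex {worst[1]})"
            )
        H_adj[yi] = 1.0 - np.exp(-(m_year * mult)[:, :, None] * rr)
        # advance the composition one year under the aligned hazards
        q = 1.0 - np.exp(-(m_year * mult)[_AGE_IDX_CAPPED][..., None] * rr)
        for m in range(12):
            if m == 0:
                _entry_add(c, entry, year)
            c -= c * q
            _age_one_month(c)
    return H_adj
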