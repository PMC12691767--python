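"""Two-step logit estimation and alignment to aggregate benefit statistics.

Step one fits a fully interactive logit for any-receipt (assessed hours
above the 65 h level-1 threshold) on age, sex and education. Step two, on
the eligible subsample, fits a logit for the upper severity band (hours at
or above 120, i.e. levels 3-7) with age interacted with sex and with
education. The fitted education gradients are then aligned to official
prevalence statistics by solving, per age×sex cell, for an additive shift
on the log-odds scale — a non-linear (monotone, hence uniquely solvable)
calibration that matches the aggregate exactly while leaving the education
odds ratios untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
import statsmodels.api as sm

from .design import (
    EDU_LABELS,
    SEX_LABELS,
    eligibility_design,
    severity_design,
)
from .prevalence import AGES, N_AGES, AlignedPrevalenceModel, PrevalenceTable

__all__ = [
    "EstimationError",
    "LogitSpec",
    "LogitFit",
    "fit_logit",
    "average_marginal_predictions",
    "align_cell",
    "build_prevalence_model",
]

ELIGIBILITY_THRESHOLD = 65.0
SEVERITY_THRESHOLD = 120.0


class EstimationError(RuntimeError):
    """Model could not be estimated (separation, rank deficiency, ...)."""


@dataclass(frozen=True)
class LogitSpec:
    """Which outcome to model and the degree of the age polynomial."""

    outcome: str  # "eligibility" | "severity"
    degree: int = 2

    def __post_init__(self) -> None:
        if self.outcome not in ("eligibility", "severity"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.degree < 0:
            raise ValueError("age polynomial degree must be >= 0")

    def build_design(self, age, sex, education):
        if self.outcome == "eligibility":
            return eligibility_design(age, sex, education, self.degree)
        return severity_design(age, sex, education, self.degree)


@dataclass(frozen=True)
class LogitFit:
    """Maximum-likelihood fit: coefficients, covariance, design recipe."""

    spec: LogitSpec
    params: np.ndarray
    cov: np.ndarray
    names: list

    def linear_predictor(self, age, sex, education) -> np.ndarray:
        X, _ = self.spec.build_design(age, sex, education)
        return X @ self.params

    def predict_proba(self, age, sex, education) -> np.ndarray:
        return expit(self.linear_predictor(age, sex, education))

    def cell_log_odds(self) -> np.ndarray:
        """Fitted log-odds on the (age, sex, education) grid, (n_ages, 2, 3)."""
        out = np.empty((N_AGES, 2, 3))
        for s in (0, 1):
            for e in (0, 1, 2):
                out[:, s, e] = self.linear_predictor(
                    AGES, np.full(N_AGES, s), np.full(N_AGES, e)
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame({"term": self.names, "coef": self.params, "se": se})

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "outcome", self.spec.outcome)
        df.insert(1, "degree", self.spec.degree)
        df.to_csv(path, index=False)


def _outcome_vector(spec: LogitSpec, survey: pd.DataFrame):
    hours = survey["assessed_hours"].to_numpy(float)
    if spec.outcome == "eligibility":
        return survey, (hours > ELIGIBILITY_THRESHOLD).astype(float)
    sub = survey[hours > ELIGIBILITY_THRESHOLD]
    return sub, (sub["assessed_hours"].to_numpy(float) >= SEVERITY_THRESHOLD).astype(float)


def fit_logit(spec: LogitSpec, survey: pd.DataFrame) -> LogitFit:
    """Fit the logit by maximum likelihood (statsmodels Newton).

    The severity model is fitted on the eligible subsample only. Constant
    outcomes, rank-deficient designs and perfect separation raise
    :class:`EstimationError` naming the offending cell where possible.
    """
    sample, y = _outcome_vector(spec, survey)
    if len(sample) == 0:
        raise EstimationError("empty estimation sample")
    if y.min() == y.max():
        raise EstimationError(
            f"{spec.outcome}: outcome is constant ({int(y[0])}) on the sample"
        )
    X, names = spec.build_design(
        sample["age"].to_numpy(), sample["sex"].to_numpy(), sample["education"].to_numpy()
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise EstimationError(
            f"{spec.outcome}: design matrix rank {rank} < {X.shape[1]} columns"
        )
    # cells with constant outcome produce separation in interactive designs
    for s in (0, 1):
        for e in (0, 1, 2):
            mask = (sample["sex"].to_numpy() == s) & (sample["education"].to_numpy() == e)
            if mask.any() and y[mask].min() == y[mask].max():
                raise EstimationError(
                    f"{spec.outcome}: outcome constant in cell "
                    f"(sex={SEX_LABELS[s]}, education={EDU_LABELS[e]})"
                )
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels internals
        raise EstimationError(f"{spec.outcome}: {exc}") from exc
    score = res.model.score(res.params)
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(score)) > 1e-3 * len(y):
        raise EstimationError(f"{spec.outcome}: optimiser did not converge")
    return LogitFit(spec, np.asarray(res.params), np.asarray(res.cov_params()), names)


def average_marginal_predictions(
    fit: LogitFit, sample: pd.DataFrame, groups=(0, 1, 2)
):
    """Mean predicted probability with education set to each group, plus
    pairwise contrasts, with delta-method standard errors.

    Returns ``(predictions, contrasts)`` DataFrames.
    """
    age = sample["age"].to_numpy()
    sex = sample["sex"].to_numpy()
    n = len(sample)
    if n == 0:
        raise ValueError("empty sample")
    values, grads = {}, {}
    for g in groups:
        edu = np.full(n, g)
        X, _ = fit.spec.build_design(age, sex, edu)
        p = expit(X @ fit.params)
        values[g] = p.mean()
        grads[g] = (p * (1 - p)) @ X / n  # d mean(p) / d beta
    pred = pd.DataFrame(
        {
            "education": [EDU_LABELS[g] for g in groups],
            "prediction": [values[g] for g in groups],
            "se": [float(np.sqrt(grads[g] @ fit.cov @ grads[g])) for g in groups],
        }
    )
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            g = grads[a] - grads[b]
            rows.append(
                (
                    f"{EDU_LABELS[a]} - {EDU_LABELS[b]}",
                    values[a] - values[b],
                    float(np.sqrt(g @ fit.cov @ g)),
                )
            )
    contrasts = pd.DataFrame(rows, columns=["contrast", "estimate", "se"])
    return pred, contrasts


def align_cell(model_log_odds, weights, target: float, tol: float = 1e-12) -> float:
    """Additive log-odds shift delta such that the weighted mean of
    logistic(log_odds + delta) equals the target prevalence.

    The weighted mean is strictly increasing in delta, so the root is
    unique. Targets of exactly 0 or 1 return -inf/+inf sentinels.
    """
    lo = np.asarray(model_log_odds, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not 0 <= target <= 1:
        raise ValueError("target prevalence must lie in [0, 1]")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    return _solve_shift(lo, w, float(target), tol)


def _solve_shift(log_odds, weights, target_sum: float, tol: float = 1e-12) -> float:
    """Solve sum_e weights_e * expit(log_odds_e + delta) = target_sum."""
    wsum = weights.sum()
    if target_sum <= 0:
        return -np.inf
    if target_sum >= wsum:
        return np.inf

    def f(d):
        return float(np.dot(weights, expit(log_odds + d)) - target_sum)

    lo_b, hi_b = -40.0, 40.0
    while f(lo_b) > 0:
        lo_b *= 2
    while f(hi_b) < 0:
        hi_b *= 2
    return brentq(f, lo_b, hi_b, xtol=tol)


def build_prevalence_model(
    elig_fit: LogitFit,
    sev_fit: LogitFit,
    stats: PrevalenceTable,
    education_weights: np.ndarray,
) -> AlignedPrevalenceModel:
    """Aligned P(level | age, sex, education) reproducing the statistics.

    Per age×sex cell: (1) the eligibility equation's education log-odds are
    shifted so the education-weighted any-receipt probability equals the
    summed level prevalences; (2) the severity equation's education
    log-odds are shifted so the weighted mass in levels 3-7 matches the
    statistics; (3) within each band, every level receives the band's
    education gradient scaled by the level's share of the band target.
    Education odds ratios from the two fitted equations are preserved
    exactly; the education-weighted aggregate reproduces the input table
    cell by cell.
    """
    w = np.asarray(education_weights, dtype=float)
    if w.shape != (N_AGES, 2, 3):
        raise ValueError("education_weights must have shape (n_ages, 2, 3)")
    if np.max(np.abs(w.sum(axis=2) - 1)) > 1e-8:
        raise ValueError("education weights must sum to 1 per age-sex cell")
    elig_lo = elig_fit.cell_log_odds()
    sev_lo = sev_fit.cell_log_odds()

    probs = np.zeros((N_AGES, 2, 3, 8))
    for i in range(N_AGES):
        for s in (0, 1):
            targets = stats.probs[i, s]  # levels 1..7
            t_any = targets.sum()
            if t_any > 1 + 1e-9:
                raise ValueError(
                    f"infeasible statistics at age {AGES[i]}, sex {s}: sum > 1"
                )
            if t_any <= 0:
                probs[i, s, :, 0] = 1.0
                continue
            ww = w[i, s]
            d_any = _solve_shift(elig_lo[i, s], ww, min(t_any, 1.0))
            p_any = expit(elig_lo[i, s] + d_any) if np.isfinite(d_any) else (
                np.ones(3) if d_any > 0 else np.zeros(3)
            )
            t_high = targets[2:].sum()
            t_low = targets[:2].sum()
            if t_high > t_any + 1e-9:
                raise ValueError(
                    f"infeasible statistics at age {AGES[i]}, sex {s}: "
                    "band prevalence exceeds any-receipt prevalence"
                )
            # weighted by per-education any-receipt: solve
            # sum_e w_e p_any_e expit(sev_lo_e + d) = t_high
            wp = ww * p_any
            if t_high <= 0:
                p_high = np.zeros(3)
            elif t_high >= wp.sum():
                p_high = np.ones(3)
            else:
                d_sev = _solve_shift(sev_lo[i, s], wp, t_high)
                p_high = expit(sev_lo[i, s] + d_sev)
            band_low = p_any * (1 - p_high)
            band_high = p_any * p_high
            for lv in range(1, 3):
                share = targets[lv - 1] / t_low if t_low > 0 else 0.0
                probs[i, s, :, lv] = band_low * share
            for lv in range(3, 8):
                share = targets[lv - 1] / t_high if t_high > 0 else 0.0
                probs[i, s, :, lv] = band_high * share
            probs[i, s, :, 0] = 1.0 - probs[i, s, :, 1:].sum(axis=1)
    return AlignedPrevalenceModel(probs, w)
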