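"""Design matrices for the eligibility and severity logit models.

Age enters as a centred, scaled polynomial (quadratic by default). The
eligibility model ("any receipt", assessed hours above the level-1
threshold) is fully interactive: a separate age polynomial per sex ×
education cell. The severity model (hours at or above 120, i.e. the
level-3..7 band, fitted on the eligible subsample) interacts age with sex
and with education but carries no three-way term.

Sex is coded 0 = male, 1 = female; education 0 = low, 1 = medium
(reference), 2 = high.
"""

from __future__ import annotations

import numpy as np

AGE_CENTER = 85.0
AGE_SCALE = 10.0

SEX_LABELS = ("male", "female")
EDU_LABELS = ("low", "medium", "high")


def age_terms(age: np.ndarray, degree: int = 2) -> np.ndarray:
    """Columns x, x^2, ... x^degree with x = (age - 85)/10.

    Degree 0 yields no columns (age-free, cell-saturated designs).
    """
    x = (np.asarray(age, dtype=float) - AGE_CENTER) / AGE_SCALE
    if degree == 0:
        return np.empty((x.shape[0], 0))
    return np.column_stack([x**k for k in range(1, degree + 1)])


def eligibility_design(age, sex, education, degree: int = 2):
    """Fully interactive design: (1, x, ..., x^d) per sex×education cell.

    Returns (X, names); X has 6*(degree+1) columns.
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=int)
    education = np.asarray(education, dtype=int)
    at = age_terms(age, degree)
    cols, names = [], []
    for s in (0, 1):
        for e in (0, 1, 2):
            cell = ((sex == s) & (education == e)).astype(float)
            cols.append(cell)
            names.append(f"{SEX_LABELS[s]}:{EDU_LABELS[e]}")
            for k in range(degree):
                cols.append(cell * at[:, k])
                names.append(f"{SEX_LABELS[s]}:{EDU_LABELS[e]}:x^{k + 1}")
    return np.column_stack(cols), names


def severity_design(age, sex, education, degree: int = 2):
    """Two-way design: age polynomial, sex, education, age×sex, age×education."""
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=int)
    education = np.asarray(education, dtype=int)
    at = age_terms(age, degree)
    female = (sex == 1).astype(float)
    low = (education == 0).astype(float)
    high = (education == 2).astype(float)
    cols = [np.ones_like(age)]
    names = ["intercept"]
    for k in range(degree):
        cols.append(at[:, k])
        names.append(f"x^{k + 1}")
    for dummy, lab in ((female, "female"), (low, "edu_low"), (high, "edu_high")):
        cols.append(dummy)
        names.append(lab)
        for k in range(degree):
            cols.append(dummy * at[:, k])
            names.append(f"{lab}:x^{k + 1}")
    return np.column_stack(cols), names


def natural_linear_predictor(coefs: dict, age, sex, education) -> np.ndarray:
    """Linear predictor from a 'natural' coefficient dict.

    Recognised keys: intercept, x, x2 (age terms on the centred/scaled
    axis), female, edu_low, edu_high, and first-order interactions
    female:x, edu_low:x, edu_high:x. This parameterisation is nested in
    both designs above, which keeps generated data inside the fitted
    model families.
    """
    age = np.asarray(age, dtype=float)
    x = (age - AGE_CENTER) / AGE_SCALE
    female = (np.asarray(sex, dtype=int) == 1).astype(float)
    edu = np.asarray(education, dtype=int)
    low = (edu == 0).astype(float)
    high = (edu == 2).astype(float)
    lp = np.full_like(age, float(coefs.get("intercept", 0.0)))
    lp = lp + coefs.get("x", 0.0) * x + coefs.get("x2", 0.0) * x**2
    lp = lp + coefs.get("female", 0.0) * female
    lp = lp + coefs.get("edu_low", 0.0) * low + coefs.get("edu_high", 0.0) * high
    lp = lp + coefs.get("female:x", 0.0) * female * x
    lp = lp + coefs.get("edu_low:x", 0.0) * low * x
    lp = lp + coefs.get("edu_high:x", 0.0) * high * x
    return lp


def natural_to_design(coefs: dict, outcome: str, degree: int = 2) -> np.ndarray:
    """Express natural coefficients in the basis of the fitted design.

    Used by parameter-recovery tests to compare fitted coefficient vectors
    with the generating truth.
    """
    g = lambda k: float(coefs.get(k, 0.0))
    if outcome == "severity":
        # basis: intercept, x.., female, female:x.., edu_low, edu_low:x..,
        # edu_high, edu_high:x..
        beta = [g("intercept"), g("x")] + ([g("x2")] if degree >= 2 else [])
        beta += [0.0] * max(0, degree - 2)
        for lab in ("female", "edu_low", "edu_high"):
            beta.append(g(lab))
            beta.append(g(f"{lab}:x"))
            beta += [0.0] * (degree - 1)
        return np.array(beta)
    if outcome == "eligibility":
        beta = []
        for s in (0, 1):
            for e in (0, 1, 2):
                female = 1.0 if s == 1 else 0.0
                low = 1.0 if e == 0 else 0.0
                high = 1.0 if e == 2 else 0.0
                icpt = (
                    g("intercept")
                    + g("female") * female
                    + g("edu_low") * low
                    + g("edu_high") * high
                )
                slope = (
                    g("x")
                    + g("female:x") * female
                    + g("edu_low:x") * low
                    + g("edu_high:x") * high
                )
                beta.append(icpt)
                beta.append(slope)
                if degree >= 2:
                    beta.append(g("x2"))
                beta += [0.0] * max(0, degree - 2)
        return np.array(beta)
    raise ValueError(f"unknown outcome {outcome!r}")
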