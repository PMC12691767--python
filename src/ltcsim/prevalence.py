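"""Containers for benefit-prevalence statistics and the aligned model.

Ages run from 65 to an open interval pooled at 105+; prevalence is stored
per single year of age, sex and allowance level 1..7 (the official-statistics
shape), or additionally per education group for the aligned model the
simulation engine draws from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AGE_MIN = 65
AGE_CAP = 105  #: open interval: all older ages pooled here
AGES = np.arange(AGE_MIN, AGE_CAP + 1)
N_AGES = len(AGES)
N_LEVELS = 7

_TOL = 1e-9


def age_index(age_years) -> np.ndarray:
    """Row index for an integer age, pooling everyone above the cap."""
    a = np.clip(np.asarray(age_years, dtype=int), AGE_MIN, AGE_CAP)
    return a - AGE_MIN


@dataclass(frozen=True)
class PrevalenceTable:
    """P(allowance level | integer age, sex) for levels 1..7.

    ``probs`` has shape (n_ages, 2, 7); rows are proper sub-distributions
    (non-negative, summing to at most 1; the remainder is level 0, no
    benefit).
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_AGES, 2, N_LEVELS):
            raise ValueError(f"expected shape {(N_AGES, 2, N_LEVELS)}, got {p.shape}")
        if np.any(p < -_TOL) or np.any(p > 1 + _TOL):
            raise ValueError("prevalence probabilities must lie in [0, 1]")
        if np.any(p.sum(axis=2) > 1 + 1e-6):
            raise ValueError("per-cell level probabilities must sum to <= 1")
        object.__setattr__(self, "probs", p)

    def any_receipt(self) -> np.ndarray:
        """P(level >= 1) by age and sex, shape (n_ages, 2)."""
        return self.probs.sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, age in enumerate(AGES):
            for s in (0, 1):
                for lv in range(1, N_LEVELS + 1):
                    rows.append((age, s, lv, self.probs[i, s, lv - 1]))
        return pd.DataFrame(rows, columns=["age", "sex", "level", "prob"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PrevalenceTable":
        p = np.zeros((N_AGES, 2, N_LEVELS))
        idx = age_index(df["age"].to_numpy())
        p[idx, df["sex"].to_numpy(int), df["level"].to_numpy(int) - 1] = df["prob"].to_numpy(float)
        return cls(p)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PrevalenceTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class AlignedPrevalenceModel:
    """P(level 0..7 | age, sex, education) after alignment, plus the
    education composition the alignment used.

    ``probs`` has shape (n_ages, 2, 3, 8) and sums to 1 over the last axis;
    ``weights`` has shape (n_ages, 2, 3) and sums to 1 over education.
    """

    probs: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if p.shape != (N_AGES, 2, 3, N_LEVELS + 1):
            raise ValueError("probs must have shape (n_ages, 2, 3, 8)")
        if w.shape != (N_AGES, 2, 3):
            raise ValueError("weights must have shape (n_ages, 2, 3)")
        if np.any(p < -_TOL):
            raise ValueError("negative level probability")
        if np.max(np.abs(p.sum(axis=3) - 1)) > 1e-6:
            raise ValueError("level probabilities must sum to 1 per cell")
        if np.max(np.abs(w.sum(axis=2) - 1)) > 1e-6:
            raise ValueError("education weights must sum to 1 per cell")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "weights", w)

    def marginal(self) -> PrevalenceTable:
        """Education-weighted aggregate; reproduces the alignment target."""
        agg = np.einsum("asel,ase->asl", self.probs[..., 1:], self.weights)
        return PrevalenceTable(np.clip(agg, 0.0, 1.0))

    def cumulative(self, education_differentials: bool = True) -> np.ndarray:
        """Cumulative level probabilities for inverse-CDF draws.

        Shape (n_ages, 2, 3, 8); when differentials are off every education
        group carries the marginal age×sex distribution.
        """
        if education_differentials:
            p = self.probs
        else:
            marg = self.marginal().probs  # (ages, 2, 7)
            p0 = 1.0 - marg.sum(axis=2, keepdims=True)
            full = np.concatenate([p0, marg], axis=2)  # (ages, 2, 8)
            p = np.broadcast_to(full[:, :, None, :], self.probs.shape)
        return np.cumsum(p, axis=-1)

    def to_frame(self) -> pd.DataFrame:
        ages, sexes, edus, levels = np.meshgrid(
            AGES, [0, 1], [0, 1, 2], np.arange(N_LEVELS + 1), indexing="ij"
        )
        return pd.DataFrame(
            {
                "age": ages.ravel(),
                "sex": sexes.ravel(),
                "education": edus.ravel(),
                "level": levels.ravel(),
                "prob": self.probs.ravel(),
                "weight": np.repeat(self.weights.ravel(), N_LEVELS + 1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlignedPrevalenceModel":
        p = np.zeros((N_AGES, 2, 3, N_LEVELS + 1))
        w = np.zeros((N_AGES, 2, 3))
        ai = age_index(df["age"].to_numpy())
        s = df["sex"].to_numpy(int)
        e = df["education"].to_numpy(int)
        lv = df["level"].to_numpy(int)
        p[ai, s, e, lv] = df["prob"].to_numpy(float)
        w[ai, s, e] = df["weight"].to_numpy(float)
        return cls(p, w)

    @classmethod
    def from_csv(cls, path) -> "AlignedPrevalenceModel":
        return cls.from_frame(pd.read_csv(path))
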