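"""Result container for a simulated scenario run.

Rather than one row per person-month, the panel stores the aggregates the
accounting module consumes losslessly: monthly recipient counts per level,
December cross-sections by age/sex/education/level, per-individual
cumulative payouts (integer cents) with entry and death timing, and the
monthly event log for conservation checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["MonthlyPanel"]


@dataclass
class MonthlyPanel:
    base_year: int
    horizon: int
    scenario: str
    seed: int
    counts: pd.DataFrame  # year, month (1..12), level (0..7), n
    december: pd.DataFrame  # year, age, sex, education, level, n
    individuals: pd.DataFrame  # id, sex, education, age_start_months,
    #                            entry_year, death_year, death_month,
    #                            cum_cents, alive
    events: pd.DataFrame  # year, month, alive_start, entries, deaths, alive_end

    @property
    def n_months(self) -> int:
        return len(self.counts[["year", "month"]].drop_duplicates())

    def years(self):
        return sorted(self.counts["year"].unique())

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "base_year": self.base_year,
            "horizon": self.horizon,
            "scenario": self.scenario,
            "seed": self.seed,
        }
        (d / "panel_meta.json").write_text(json.dumps(meta, indent=1))
        self.counts.to_csv(d / "counts.csv", index=False)
        self.december.to_csv(d / "december.csv", index=False)
        self.individuals.to_csv(d / "individuals.csv", index=False)
        self.events.to_csv(d / "events.csv", index=False)

    @classmethod
    def load(cls, directory) -> "MonthlyPanel":
        d = Path(directory)
        meta = json.loads((d / "panel_meta.json").read_text())
        return cls(
            base_year=meta["base_year"],
            horizon=meta["horizon"],
            scenario=meta["scenario"],
            seed=meta["seed"],
            counts=pd.read_csv(d / "counts.csv"),
            december=pd.read_csv(d / "december.csv"),
            individuals=pd.read_csv(d / "individuals.csv"),
            events=pd.read_csv(d / "events.csv"),
        )
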