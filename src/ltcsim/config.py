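"""Configuration: defaults, YAML loading, and construction of the
generator objects.

One structured file drives the whole pipeline (sections ``population``,
``survey``, ``mortality``, ``entry``, ``simulation``). Seeds are never part
of the file: the pipeline derives per-stream seeds deterministically from
one global seed, so the same seed reproduces every stage byte for byte and
scenario comparisons share common random numbers.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

from .synthetic import (
    DEFAULT_ELIGIBILITY_COEFS,
    DEFAULT_SEVERITY_COEFS,
    DEFAULT_FLAG_PROBS,
    EntrySchedule,
    MortalitySchedule,
    PopulationConfig,
    SurveyConfig,
)

__all__ = [
    "default_config",
    "load_config",
    "population_config",
    "survey_config",
    "mortality_schedule",
    "entry_schedule",
    "derive_seeds",
]


def default_config() -> dict:
    return {
        "population": {
            "n_individuals": 10_000,
            "base_year": 2025,
            "age_range": [65, 105],
            "sex_share": None,
            "age_weights": "decline",
        },
        "survey": {
            "n_respondents": 20_000,
            "eligibility_coefficients": dict(DEFAULT_ELIGIBILITY_COEFS),
            "severity_coefficients": dict(DEFAULT_SEVERITY_COEFS),
            "level_split_low": [0.55, 0.45],
            "level_split_high": [0.50, 0.20, 0.30],
            "flag_probs": dict(DEFAULT_FLAG_PROBS),
            "dementia_base": 0.01,
            "dementia_growth": 0.09,
            "dementia_cap": 0.5,
        },
        "mortality": {
            "rate_at_65": [0.013, 0.008],
            "log_slope": 0.095,
            "annual_improvement": 0.985,
            "education_rr": [1.25, 1.0, 0.8],
        },
        "entry": {
            "base_size": 500,
            "growth": 0.01,
            "start_composition": [0.28, 0.49, 0.23],
            "end_composition": [0.15, 0.50, 0.35],
            "female_share": 0.52,
        },
        "simulation": {
            "horizon": 2080,
        },
    }


def load_config(path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in user.items():
        if section not in cfg:
            raise KeyError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise TypeError(f"config section {section!r} must be a mapping")
        merged = copy.deepcopy(cfg[section])
        merged.update(values)
        cfg[section] = merged
    return cfg


def population_config(cfg: dict, seed: int) -> PopulationConfig:
    p = cfg["population"]
    return PopulationConfig(
        n_individuals=int(p["n_individuals"]),
        base_year=int(p["base_year"]),
        age_range=tuple(p["age_range"]),
        sex_share=p.get("sex_share"),
        age_weights=p.get("age_weights", "decline"),
        seed=seed,
    )


def survey_config(cfg: dict, seed: int) -> SurveyConfig:
    s = cfg["survey"]
    return SurveyConfig(
        n_respondents=int(s["n_respondents"]),
        eligibility_coefficients=dict(s["eligibility_coefficients"]),
        severity_coefficients=dict(s["severity_coefficients"]),
        level_split_low=tuple(s["level_split_low"]),
        level_split_high=tuple(s["level_split_high"]),
        flag_probs=dict(s["flag_probs"]),
        dementia_base=float(s["dementia_base"]),
        dementia_growth=float(s["dementia_growth"]),
        dementia_cap=float(s["dementia_cap"]),
        seed=seed,
    )


def mortality_schedule(cfg: dict) -> MortalitySchedule:
    m = cfg["mortality"]
    return MortalitySchedule.gompertz(
        rate_at_65=tuple(m["rate_at_65"]),
        log_slope=float(m["log_slope"]),
        annual_improvement=float(m["annual_improvement"]),
        education_rr=tuple(m["education_rr"]),
    )


def entry_schedule(cfg: dict) -> EntrySchedule:
    e = cfg["entry"]
    base_year = int(cfg["population"]["base_year"])
    horizon = int(cfg["simulation"]["horizon"])
    return EntrySchedule.expansion(
        start_year=base_year + 1,
        end_year=horizon,
        base_size=int(e["base_size"]),
        growth=float(e["growth"]),
        start_composition=tuple(e["start_composition"]),
        end_composition=tuple(e["end_composition"]),
        female_share=float(e["female_share"]),
    )


def derive_seeds(seed: int) -> dict:
    """Deterministic expansion of one global seed into named stream seeds.

    Stream k gets the first word of ``SeedSequence([seed, k])``, reduced
    below 2**31. The simulation seed is shared by all scenarios so they run
    under common random numbers.
    """
    names = ("population", "survey", "simulation")
    return {
        name: int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        for k, name in enumerate(names)
    }
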