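"""End-to-end pipeline: generate -> estimate -> simulate (per scenario) ->
report, with every stage reading only the serialised outputs of earlier
stages, plus a run manifest for reproducibility.

The manifest records the config hash, the derived per-stream seeds and the
checksum of every output file: identical manifests imply byte-identical
outputs, and any intermediate file can be deleted and regenerated from the
manifest's config and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import accounting, config as config_mod, engine, estimation, projection, synthetic
from .assessment import DEFAULT_RULES
from .panel import MonthlyPanel
from .prevalence import AGES, N_AGES, AlignedPrevalenceModel, PrevalenceTable

__all__ = [
    "run_pipeline",
    "stage_generate",
    "stage_estimate",
    "stage_simulate",
    "stage_report",
]


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _weights_to_csv(weights: np.ndarray, path: Path) -> None:
    a, s, e = np.meshgrid(AGES, [0, 1], [0, 1, 2], indexing="ij")
    pd.DataFrame(
        {"age": a.ravel(), "sex": s.ravel(), "education": e.ravel(),
         "weight": weights.ravel()}
    ).to_csv(path, index=False)


def _weights_from_csv(path: Path) -> np.ndarray:
    df = pd.read_csv(path)
    w = np.zeros((N_AGES, 2, 3))
    w[df["age"] - AGES[0], df["sex"], df["education"]] = df["weight"]
    return w


def stage_generate(cfg: dict, seeds: dict, outdir: Path) -> list:
    """Write population, survey, prevalence targets, death targets and the
    base-year education composition."""
    outdir.mkdir(parents=True, exist_ok=True)
    pop_cfg = config_mod.population_config(cfg, seeds["population"])
    svy_cfg = config_mod.survey_config(cfg, seeds["survey"])
    mort = config_mod.mortality_schedule(cfg)
    entry = config_mod.entry_schedule(cfg)
    horizon = int(cfg["simulation"]["horizon"])

    synthetic.generate_population(pop_cfg).to_csv(outdir / "population.csv", index=False)
    synthetic.generate_survey(svy_cfg).to_csv(outdir / "survey.csv", index=False)
    table, deaths = synthetic.generate_targets(pop_cfg, mort, entry, svy_cfg, horizon)
    table.to_csv(outdir / "prevalence_targets.csv")
    deaths.to_csv(outdir / "deaths_targets.csv", index=False)
    _weights_to_csv(synthetic.education_weights(pop_cfg), outdir / "education_weights.csv")
    return [
        "population.csv",
        "survey.csv",
        "prevalence_targets.csv",
        "deaths_targets.csv",
        "education_weights.csv",
    ]


def stage_estimate(cfg: dict, outdir: Path) -> list:
    """Fit the two logits on the stored survey and align to the stored
    prevalence targets; serialise fits and the aligned model."""
    survey = pd.read_csv(outdir / "survey.csv")
    stats = PrevalenceTable.from_csv(outdir / "prevalence_targets.csv")
    weights = _weights_from_csv(outdir / "education_weights.csv")
    elig = estimation.fit_logit(estimation.LogitSpec("eligibility"), survey)
    sev = estimation.fit_logit(estimation.LogitSpec("severity"), survey)
    elig.to_csv(outdir / "fit_eligibility.csv")
    sev.to_csv(outdir / "fit_severity.csv")
    model = estimation.build_prevalence_model(elig, sev, stats, weights)
    model.to_csv(outdir / "aligned_model.csv")
    return ["fit_eligibility.csv", "fit_severity.csv", "aligned_model.csv"]


def stage_simulate(cfg: dict, seeds: dict, outdir: Path, scenario_name: str) -> list:
    """Align mortality to the stored death targets and run one scenario."""
    scenario = engine.SCENARIOS[scenario_name]
    pop_cfg = config_mod.population_config(cfg, seeds["population"])
    mort = config_mod.mortality_schedule(cfg)
    entry = config_mod.entry_schedule(cfg)
    horizon = int(cfg["simulation"]["horizon"])
    base_year = pop_cfg.base_year
    n_years = horizon - base_year + 1

    population = pd.read_csv(outdir / "population.csv")
    model = AlignedPrevalenceModel.from_csv(outdir / "aligned_model.csv")
    deaths_df = pd.read_csv(outdir / "deaths_targets.csv")
    targets = projection.deaths_from_frame(deaths_df, base_year, n_years)
    c0 = projection.expected_initial_counts(pop_cfg)
    hazards = projection.align_mortality(mort, c0, entry, targets, base_year)

    panel = engine.run_scenario(
        population,
        scenario,
        hazards,
        entry,
        model,
        horizon=horizon,
        base_year=base_year,
        seed=seeds["simulation"],
    )
    panel.save(outdir / scenario_name)
    return [f"{scenario_name}/{f}" for f in
            ("panel_meta.json", "counts.csv", "december.csv", "individuals.csv",
             "events.csv")]


def stage_report(cfg: dict, outdir: Path, scenario_name: str) -> list:
    """Regenerate the three reports from a stored panel."""
    panel = MonthlyPanel.load(outdir / scenario_name)
    horizon = int(cfg["simulation"]["horizon"])
    exp = accounting.annual_expenditure(panel, DEFAULT_RULES)
    exp.table.assign(total=exp.totals).to_csv(outdir / f"expenditure_{scenario_name}.csv")
    accounting.lifetime_costs(panel).to_csv(
        outdir / f"lifetime_costs_{scenario_name}.csv", index=False
    )
    accounting.prevalence_report(panel, horizon).to_csv(
        outdir / f"prevalence_{horizon}_{scenario_name}.csv", index=False
    )
    summary = {
        "scenario": scenario_name,
        "seed": panel.seed,
        "total_expenditure_final_year_eur": exp.total(horizon),
        "total_expenditure_base_year_eur": exp.total(panel.base_year),
    }
    (outdir / f"summary_{scenario_name}.json").write_text(json.dumps(summary, indent=1))
    return [
        f"expenditure_{scenario_name}.csv",
        f"lifetime_costs_{scenario_name}.csv",
        f"prevalence_{horizon}_{scenario_name}.csv",
        f"summary_{scenario_name}.json",
    ]


def run_pipeline(cfg: dict, scenarios, seed: int, outdir) -> dict:
    """Run every stage in order for the requested scenarios and write the
    manifest. Returns the manifest dict."""
    outdir = Path(outdir)
    seeds = config_mod.derive_seeds(seed)
    files = stage_generate(cfg, seeds, outdir)
    files += stage_estimate(cfg, outdir)
    for name in scenarios:
        files += stage_simulate(cfg, seeds, outdir, name)
        files += stage_report(cfg, outdir, name)
    manifest = {
        "config_hash": _config_hash(cfg),
        "global_seed": seed,
        "stream_seeds": seeds,
        "scenarios": list(scenarios),
        "outputs": {f: _file_checksum(outdir / f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
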