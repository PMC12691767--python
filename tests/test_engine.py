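"""Simulation engine: care-age map, mortality alignment, monthly stepping,
conservation, and the cross-sectional (no-persistence) imputation design."""

import numpy as np
import pandas as pd
import pytest

from conftest import uniform_level_model
from ltcsim import engine, projection, synthetic
from ltcsim.engine import (
    SCENARIOS,
    InfeasibleTargetError,
    ScenarioConfig,
    care_age,
    run_scenario,
    solve_baseline_hazard,
    step_month,
)
from ltcsim.prevalence import N_AGES


class TestCareAge:
    @pytest.mark.parametrize("age,factor,expected", [
        (70, 0.8, 69.0),
        (65, 0.8, 65.0),
        (90, 0.8, 85.0),
        (75, 1.0, 75.0),
        (75, 0.8, 73.0),
    ])
    def test_examples(self, age, factor, expected):
        assert care_age(age, factor) == expected

    def test_below_anchor_rejected(self):
        with pytest.raises(ValueError):
            care_age(60, 0.8)

    def test_vectorised(self):
        ages = np.array([65.0, 70.0, 90.0])
        assert np.allclose(care_age(ages, 0.8), [65, 69, 85])


class TestScenarioConfig:
    def test_presets(self):
        assert SCENARIOS["S0"].education_differentials
        assert not SCENARIOS["S1"].education_differentials
        assert SCENARIOS["S2"].care_age_factor == 0.8
        assert SCENARIOS["S3"].mortality_mode == "constant_base_year"

    def test_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig("bad", care_age_factor=0.0)
        with pytest.raises(ValueError):
            ScenarioConfig("bad", mortality_mode="frozen")


class TestMortalityAlignment:
    def test_closed_form_uniform_rr(self):
        assert solve_baseline_hazard([100, 100, 100], [1, 1, 1], 30) == pytest.approx(0.1)

    def test_closed_form_two_groups(self):
        # 100*2h + 100*h = 15  =>  h = 0.05
        assert solve_baseline_hazard([100, 100], [2, 1], 15) == pytest.approx(0.05)

    def test_infeasible_target(self):
        with pytest.raises(InfeasibleTargetError):
            solve_baseline_hazard([10, 10], [1, 1], 25)

    def test_round_trip_recovers_schedule(self, chain):
        """Targets generated from the schedule itself align to multipliers
        of one: the adjusted hazards equal the schedule's own."""
        H0 = chain.mort.hazard_array(chain.base_year, chain.horizon - chain.base_year + 1)
        assert np.allclose(chain.hazards, H0, rtol=1e-9)

    def test_relative_risks_persist(self, chain):
        m = -np.log1p(-chain.hazards)
        assert np.allclose(m[..., 0] / m[..., 1], 1.25)
        assert np.allclose(m[..., 2] / m[..., 1], 0.8)

    def test_excessive_targets_raise(self, chain):
        bad = chain.death_targets.copy()
        bad[0] *= 50.0  # far beyond the population at risk
        with pytest.raises(InfeasibleTargetError):
            projection.align_mortality(
                chain.mort, chain.c0, chain.entry, bad[:1], chain.base_year
            )

    def test_monte_carlo_deaths_match_targets(self, chain, small_entry):
        """Simulated first-year deaths across 40 seeded runs match the
        aligned expectation within a Poisson-scale bound per age band."""
        reps = 40
        totals = np.zeros((N_AGES, 2))
        model = uniform_level_model(1, 0.0)
        for k in range(reps):
            pop = synthetic.generate_population(
                synthetic.PopulationConfig(n_individuals=4000, seed=900 + k)
            )
            panel = run_scenario(
                pop, SCENARIOS["S0"], chain.hazards, small_entry, model,
                horizon=chain.base_year, base_year=chain.base_year, seed=300 + k,
            )
            totals += _death_grid(panel)
        c0 = projection.expected_initial_counts(
            synthetic.PopulationConfig(n_individuals=4000)
        )
        expected = projection.project(
            c0, chain.hazards, small_entry, chain.base_year, chain.base_year
        )["deaths"][0]
        # pool ages into 5-year bands to keep expectations away from zero
        bands = np.arange(N_AGES) // 5
        for b in np.unique(bands):
            for s in (0, 1):
                t = expected[bands == b, s].sum() * reps
                x = totals[bands == b, s].sum()
                assert abs(x - t) <= 3 * np.sqrt(max(t, 1.0)) + 3


def _death_grid(panel):
    """Deaths by (age index, sex) reconstructed from the individuals frame."""
    from ltcsim.prevalence import AGE_CAP, AGE_MIN

    ind = panel.individuals
    dead = ind[ind.death_year >= 0]
    grid = np.zeros((N_AGES, 2))
    months_elapsed = (dead.death_year - panel.base_year) * 12 + dead.death_month - 1
    age_at_death = (dead.age_start_months + months_elapsed) // 12
    ai = np.clip(age_at_death, AGE_MIN, AGE_CAP) - AGE_MIN
    np.add.at(grid, (ai.to_numpy(int), dead.sex.to_numpy(int)), 1)
    return grid


class TestStepAndRun:
    def test_single_level_payout_accrual(self, chain, small_entry):
        """With zero mortality and a degenerate all-level-1 model, every
        survivor accrues 12 x 200.80 EUR over a year."""
        pop = synthetic.generate_population(
            synthetic.PopulationConfig(n_individuals=50, seed=1)
        )
        hazards = np.zeros((1, N_AGES, 2, 3))
        model = uniform_level_model(1, 1.0)
        panel = run_scenario(pop, SCENARIOS["S0"], hazards, small_entry, model,
                             horizon=2025, base_year=2025, seed=2)
        assert (panel.individuals["cum_cents"] == 12 * 20080).all()
        assert panel.individuals["alive"].all()

    def test_horizon_equals_base_year_gives_12_months(self, chain, small_entry):
        pop = synthetic.generate_population(
            synthetic.PopulationConfig(n_individuals=20, seed=1)
        )
        panel = run_scenario(pop, SCENARIOS["S0"], chain.hazards, small_entry,
                             chain.model, horizon=2025, base_year=2025, seed=2)
        assert panel.n_months == 12

    def test_zero_prevalence_means_zero_payouts(self, chain, small_entry):
        pop = synthetic.generate_population(
            synthetic.PopulationConfig(n_individuals=100, seed=1)
        )
        model = uniform_level_model(1, 0.0)
        panel = run_scenario(pop, SCENARIOS["S0"], chain.hazards, small_entry,
                             model, horizon=2026, base_year=2025, seed=2)
        assert (panel.individuals["cum_cents"] == 0).all()
        assert panel.counts[panel.counts.level > 0]["n"].sum() == 0

    def test_event_log_conservation(self, panel_s0):
        """Deaths + survivors + entries reconcile exactly every month."""
        ev = panel_s0.events
        assert (ev["alive_end"] == ev["alive_start"] - ev["deaths"]).all()
        carried = ev["alive_end"].shift(1).iloc[1:]
        assert (ev["alive_start"].iloc[1:] == carried + ev["entries"].iloc[1:]).all()
        ind = panel_s0.individuals
        assert len(ind) == 10_000 + ev["entries"].sum()
        assert (~ind["alive"]).sum() == ev["deaths"].sum()

    def test_cross_sectional_share_matches_model(self, chain, small_entry):
        """Monthly level shares in a fixed cell match the model probability
        within a binomial bound (cross-sectional imputation)."""
        n = 5000
        pop = pd.DataFrame({
            "id": np.arange(n), "age_months": np.full(n, 80 * 12),
            "sex": np.zeros(n, np.int8), "education": np.ones(n, np.int8),
        })
        hazards = np.zeros((1, N_AGES, 2, 3))
        panel = run_scenario(pop, SCENARIOS["S0"], hazards, small_entry,
                             chain.model, horizon=2025, base_year=2025, seed=9)
        counts = panel.counts.groupby("level")["n"].sum()
        total = counts.sum()
        probs = chain.model.probs[80 - 65, 0, 1]
        for lv in range(8):
            p = probs[lv]
            se = np.sqrt(max(p * (1 - p), 1e-12) / total)
            assert abs(counts.get(lv, 0) / total - p) < 3 * se + 0.5 / total

    def test_no_longitudinal_persistence(self, chain, small_entry):
        """P(level_t = l and level_{t-1} = l) equals P(l)^2: consecutive
        months are independent draws, as the cross-sectional design states."""
        n = 8000
        pop = pd.DataFrame({
            "id": np.arange(n), "age_months": np.full(n, 85 * 12),
            "sex": np.ones(n, np.int8), "education": np.ones(n, np.int8),
        })
        hazards = np.zeros((2, N_AGES, 2, 3))
        state = engine.SimulationState.from_population(pop, 2025, 2025, seed=4)
        sc = SCENARIOS["S0"]
        step_month(state, sc, hazards, small_entry, chain.model)
        prev = state.level.copy()
        step_month(state, sc, hazards, small_entry, chain.model)
        # ages moved one month; probabilities still from the age-85 row
        probs = chain.model.probs[85 - 65, 1, 1]
        for lv in (0, 1, 2):
            p = probs[lv]
            joint = np.mean((prev == lv) & (state.level == lv))
            se = np.sqrt(max(p**2 * (1 - p**2), 1e-12) / n)
            assert abs(joint - p**2) < 3 * se + 0.5 / n

    def test_deterministic_given_seed(self, chain, small_entry):
        pop = synthetic.generate_population(
            synthetic.PopulationConfig(n_individuals=200, seed=1)
        )
        kw = dict(horizon=2027, base_year=2025, seed=5)
        a = run_scenario(pop, SCENARIOS["S2"], chain.hazards, small_entry,
                         chain.model, **kw)
        b = run_scenario(pop, SCENARIOS["S2"], chain.hazards, small_entry,
                         chain.model, **kw)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.individuals, b.individuals)

    def test_hazard_horizon_checked(self, chain, small_entry):
        pop = synthetic.generate_population(
            synthetic.PopulationConfig(n_individuals=10, seed=1)
        )
        with pytest.raises(ValueError):
            run_scenario(pop, SCENARIOS["S0"], chain.hazards[:1], small_entry,
                         chain.model, horizon=2030, base_year=2025, seed=5)


class TestStationarity:
    def test_constant_renewal_stabilises(self):
        """Constant hazards and constant entry cohorts drive the expected
        65+ population to a stationary level (renewal theory): the relative
        change falls below 1% per decade after a lifespan of burn-in."""
        mort = synthetic.MortalitySchedule.gompertz(annual_improvement=1.0)
        entry = synthetic.EntrySchedule(
            years=np.arange(2026, 2126),
            cohort_size=np.full(100, 200),
            education_composition=np.tile([0.3, 0.5, 0.2], (100, 1)),
        )
        pop_cfg = synthetic.PopulationConfig(n_individuals=4000)
        c0 = projection.expected_initial_counts(pop_cfg)
        H = mort.hazard_array(2025, 101)
        sizes = []
        c = c0.copy()
        for yi in range(101):
            res = projection.project(c, H[yi:yi + 1], entry, 2025 + yi, 2025 + yi)
            c = res["final_counts"]
            sizes.append(c.sum())
        sizes = np.array(sizes)
        for start in (60, 70, 80, 90):
            rel = abs(sizes[start + 10] / sizes[start] - 1)
            assert rel < 0.01
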