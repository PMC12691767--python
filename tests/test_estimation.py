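"""Logit fitting, average marginal predictions, and alignment."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from ltcsim import estimation, synthetic
from ltcsim.estimation import (
    EstimationError,
    LogitSpec,
    align_cell,
    average_marginal_predictions,
    build_prevalence_model,
    fit_logit,
)
from ltcsim.prevalence import AGES, N_AGES, PrevalenceTable


def _mini_survey(hours, age=None, sex=None, education=None):
    n = len(hours)
    return pd.DataFrame(
        {
            "age": age if age is not None else np.full(n, 80),
            "sex": sex if sex is not None else np.zeros(n, int),
            "education": education if education is not None else np.ones(n, int),
            "assessed_hours": hours,
        }
    )


class TestFitLogit:
    def test_saturated_cell_model_recovers_cell_means(self):
        """With no age terms the eligibility design is saturated on the six
        sex×education cells, so the ML fit reproduces every cell mean."""
        rng = np.random.default_rng(0)
        n = 3000
        sex = rng.integers(0, 2, n)
        edu = rng.integers(0, 3, n)
        p = 0.2 + 0.1 * sex + 0.05 * edu
        hours = np.where(rng.random(n) < p, 80.0, 30.0)
        df = _mini_survey(hours, age=np.full(n, 80), sex=sex, education=edu)
        fit = fit_logit(LogitSpec("eligibility", degree=0), df)
        for s in (0, 1):
            for e in (0, 1, 2):
                cell = df[(df.sex == s) & (df.education == e)]
                observed = (cell["assessed_hours"] > 65).mean()
                predicted = fit.predict_proba(
                    np.array([80]), np.array([s]), np.array([e])
                )[0]
                assert predicted == pytest.approx(observed, abs=1e-6)

    def test_constant_outcome_raises(self):
        df = _mini_survey(np.full(100, 30.0))
        with pytest.raises(EstimationError, match="constant"):
            fit_logit(LogitSpec("eligibility"), df)

    def test_constant_cell_raises_naming_cell(self):
        rng = np.random.default_rng(1)
        n = 600
        sex = rng.integers(0, 2, n)
        edu = rng.integers(0, 3, n)
        hours = np.where(rng.random(n) < 0.4, 80.0, 30.0)
        hours[(sex == 1) & (edu == 2)] = 30.0  # empty outcome in one cell
        df = _mini_survey(hours, age=rng.integers(65, 100, n), sex=sex, education=edu)
        with pytest.raises(EstimationError, match="female.*high"):
            fit_logit(LogitSpec("eligibility"), df)

    def test_severity_fits_on_eligible_subsample(self, chain):
        assert chain.sev.spec.outcome == "severity"
        p = chain.sev.predict_proba(np.array([85]), np.array([1]), np.array([1]))
        assert 0 < p[0] < 1

    def test_recovery_single_seed(self, chain):
        """Fitted probabilities track the generating logits on the grid."""
        cfg = chain.svy_cfg
        for fit, probfn in ((chain.elig, cfg.eligibility_prob),
                            (chain.sev, cfg.severity_prob)):
            for s in (0, 1):
                for e in (0, 1, 2):
                    est = fit.predict_proba(AGES, np.full(N_AGES, s), np.full(N_AGES, e))
                    true = probfn(AGES, np.full(N_AGES, s), np.full(N_AGES, e))
                    assert np.mean(np.abs(est - true)) < 0.03


class TestAverageMarginalPredictions:
    def test_zero_education_coefficients_give_equal_groups(self):
        cfg = synthetic.SurveyConfig(
            n_respondents=4000,
            eligibility_coefficients={"intercept": -1.0, "x": 0.5},
            seed=5,
        )
        df = synthetic.generate_survey(cfg)
        fit = fit_logit(LogitSpec("severity"), df)
        # zero out the education terms of the fitted model
        params = fit.params.copy()
        for i, name in enumerate(fit.names):
            if "edu" in name:
                params[i] = 0.0
        fit0 = estimation.LogitFit(fit.spec, params, fit.cov, fit.names)
        pred, contrasts = average_marginal_predictions(fit0, df)
        assert pred["prediction"].nunique() == 1
        assert np.allclose(contrasts["estimate"], 0.0)

    def test_two_row_hand_calculation(self):
        spec = LogitSpec("severity", degree=1)
        # coefficient vector chosen by hand; design: 1, x, F, Fx, L, Lx, H, Hx
        params = np.array([0.3, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        fit = estimation.LogitFit(spec, params, np.eye(8) * 1e-4,
                                  [f"b{i}" for i in range(8)])
        sample = pd.DataFrame(
            {"age": [75.0, 95.0], "sex": [0, 0], "education": [1, 1]}
        )
        pred, _ = average_marginal_predictions(fit, sample, groups=(1,))
        x = (np.array([75.0, 95.0]) - 85.0) / 10.0
        expected = expit(0.3 + 0.5 * x).mean()
        assert pred["prediction"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_delta_method_vs_bootstrap(self):
        """Delta-method SEs of the group predictions agree with a
        nonparametric bootstrap within 15%."""
        cfg = synthetic.SurveyConfig(n_respondents=1500, seed=8)
        df = synthetic.generate_survey(cfg)
        spec = LogitSpec("eligibility", degree=1)
        fit = fit_logit(spec, df)
        pred, _ = average_marginal_predictions(fit, df)
        rng = np.random.default_rng(17)
        boot = []
        for _ in range(500):
            sample = df.sample(len(df), replace=True, random_state=rng.integers(2**31))
            bfit = fit_logit(spec, sample)
            bpred, _ = average_marginal_predictions(bfit, sample)
            boot.append(bpred["prediction"].to_numpy())
        boot_se = np.std(np.array(boot), axis=0, ddof=1)
        delta_se = pred["se"].to_numpy()
        assert np.all(np.abs(delta_se / boot_se - 1) < 0.15)

    def test_empty_sample_raises(self, chain):
        with pytest.raises(ValueError):
            average_marginal_predictions(chain.elig, chain.survey.iloc[:0])


class TestAlignCell:
    def test_zero_shift_when_target_matches(self):
        lo = np.array([-1.0, 0.0, 1.0])
        w = np.array([0.3, 0.4, 0.3])
        target = float(np.dot(w, expit(lo)))
        assert align_cell(lo, w, target) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_single_group(self):
        # one group at p=0.5 aligned to 0.25: shift is logit(0.25)
        delta = align_cell(np.array([0.0]), np.array([1.0]), 0.25)
        assert delta == pytest.approx(float(logit(0.25)), abs=1e-9)
        assert delta == pytest.approx(-1.0986, abs=1e-4)

    def test_root_vs_grid_search(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            lo = rng.normal(0, 1.5, 3)
            w = rng.dirichlet(np.ones(3))
            target = rng.uniform(0.05, 0.95)
            delta = align_cell(lo, w, target)
            grid = np.arange(-12.0, 12.0, 1e-6)
            vals = np.abs(expit(lo[None, :] + grid[:, None]) @ w - target)
            assert abs(delta - grid[np.argmin(vals)]) < 1e-5

    def test_boundary_targets(self):
        lo, w = np.array([0.0, 0.5]), np.array([0.5, 0.5])
        assert align_cell(lo, w, 0.0) == -np.inf
        assert align_cell(lo, w, 1.0) == np.inf
        with pytest.raises(ValueError):
            align_cell(lo, w, 1.5)
        with pytest.raises(ValueError):
            align_cell(lo, np.array([0.5, 0.2]), 0.5)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        lo=st.lists(st.floats(-4, 4), min_size=3, max_size=3),
        w_raw=st.lists(st.floats(0.05, 1), min_size=3, max_size=3),
        target=st.floats(0.01, 0.99),
    )
    def test_alignment_preserves_odds_ratios(self, lo, w_raw, target):
        """The shift is additive on the log-odds scale, so education odds
        ratios are untouched and the target is met to solver precision."""
        lo = np.array(lo)
        w = np.array(w_raw) / np.sum(w_raw)
        delta = align_cell(lo, w, target)
        post = expit(lo + delta)
        assert abs(float(np.dot(w, post)) - target) < 1e-10
        odds = post / (1 - post)
        pre = np.exp(lo)
        assert np.allclose(np.log(odds / odds[1]), np.log(pre / pre[1]), atol=1e-8)


class TestBuildPrevalenceModel:
    def test_zero_statistics_collapse(self, chain):
        zero = PrevalenceTable(np.zeros((N_AGES, 2, 7)))
        model = build_prevalence_model(chain.elig, chain.sev, zero, chain.weights)
        assert np.all(model.probs[..., 0] == 1.0)

    def test_zero_education_fit_collapses_to_statistics(self, chain):
        """Education-blind fits make the aligned model equal the statistics
        in every education group."""
        def strip_education(fit):
            params = fit.params.copy()
            if fit.spec.outcome == "severity":
                for i, name in enumerate(fit.names):
                    if "edu" in name:
                        params[i] = 0.0
            else:
                # average the cell blocks so all cells share one profile
                k = len(params) // 6
                blocks = params.reshape(6, k)
                params = np.tile(blocks.mean(axis=0), 6)
            return estimation.LogitFit(fit.spec, params, fit.cov, fit.names)

        model = build_prevalence_model(
            strip_education(chain.elig), strip_education(chain.sev),
            chain.table, chain.weights,
        )
        for e in (0, 1, 2):
            assert np.allclose(model.probs[:, :, e, 1:], chain.table.probs, atol=1e-8)

    def test_aggregation_identity(self, chain):
        """Education-weighted aggregation of the aligned model reproduces
        the input statistics."""
        agg = chain.model.marginal()
        assert np.max(np.abs(agg.probs - chain.table.probs)) < 1e-8

    def test_education_odds_ratios_preserved(self, chain):
        """Within each cell the any-receipt odds ratios across education
        equal those of the fitted eligibility equation."""
        elig_lo = chain.elig.cell_log_odds()
        p_any = chain.model.probs[..., 1:].sum(axis=3)
        mask = (p_any > 1e-8) & (p_any < 1 - 1e-8)
        log_odds = np.where(mask, np.log(p_any / (1 - p_any)), np.nan)
        for i in range(0, N_AGES, 10):
            for s in (0, 1):
                if not mask[i, s].all():
                    continue
                model_or = log_odds[i, s] - log_odds[i, s, 1]
                fit_or = elig_lo[i, s] - elig_lo[i, s, 1]
                assert np.allclose(model_or, fit_or, atol=1e-7)

    def test_chain_parameter_recovery_mae(self, chain):
        """Full estimation chain recovers the generating per-education level
        probabilities with mean absolute error below 0.01."""
        cfg = chain.svy_cfg
        errs = []
        for s in (0, 1):
            for e in (0, 1, 2):
                true = synthetic.closed_form_level_probs(
                    cfg, AGES, np.full(N_AGES, s), np.full(N_AGES, e)
                )
                errs.append(np.abs(chain.model.probs[:, s, e, :] - true))
        assert np.mean(errs) < 0.01

    def test_infeasible_statistics_rejected(self, chain):
        bad = chain.table.probs.copy()
        bad[10, 0, :] = 0.2  # sums to 1.4 > 1
        with pytest.raises(ValueError):
            PrevalenceTable(bad)
        with pytest.raises(ValueError):
            build_prevalence_model(chain.elig, chain.sev, chain.table,
                                   np.full((N_AGES, 2, 3), 0.5))
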