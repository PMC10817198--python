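"""Calibration of income means against poverty statistics."""

import dataclasses
import math

import numpy as np
import pytest

from cherisk.calibrate import (
    DAYS_PER_YEAR,
    GridConfig,
    calibrate_mean,
    calibrate_proxies,
    candidate_grid,
    choose_proxy,
    replicate_poverty_stats,
)
from cherisk.income import make_income_model, poverty_gap, poverty_headcount

LINE = 1.90 * DAYS_PER_YEAR
GAP_LINE = 2.15 * DAYS_PER_YEAR


class TestReplicateStats:
    def test_matches_closed_form_within_monte_carlo_error(self):
        m = make_income_model(1200.0, 0.42)
        reps, draws = 25, 10_000
        hc, gap = replicate_poverty_stats(m, LINE, reps=reps, draws_per_rep=draws, seed=3)
        n = reps * draws
        true_hc = poverty_headcount(m, LINE)
        true_gap = poverty_gap(m, LINE)
        se_hc = math.sqrt(true_hc * (1 - true_hc) / n)
        assert abs(hc - true_hc) < 3 * se_hc
        # per-draw shortfall is in [0,1], so Var <= E[g] and SE <= sqrt(gap/n)
        assert abs(gap - true_gap) < 3 * math.sqrt(true_gap / n)

    def test_deterministic_given_seed(self):
        m = make_income_model(900.0, 0.5)
        a = replicate_poverty_stats(m, LINE, seed=11)
        b = replicate_poverty_stats(m, LINE, seed=11)
        assert a == b

    def test_converges_with_more_draws(self):
        m = make_income_model(1000.0, 0.45)
        true_hc = poverty_headcount(m, LINE)
        hc_small, _ = replicate_poverty_stats(m, LINE, reps=25, draws_per_rep=10**3, seed=1)
        hc_large, _ = replicate_poverty_stats(m, LINE, reps=25, draws_per_rep=10**5, seed=1)
        assert abs(hc_large - true_hc) < abs(hc_small - true_hc) + 1e-3

    def test_tiny_line_gives_zero_stats(self):
        m = make_income_model(1000.0, 0.45)
        hc, gap = replicate_poverty_stats(m, 1e-9, seed=2)
        assert hc == 0.0 and gap == pytest.approx(0.0, abs=1e-9)

    def test_rejects_bad_inputs(self):
        m = make_income_model(1000.0, 0.45)
        with pytest.raises(ValueError):
            replicate_poverty_stats(m, 0.0)
        with pytest.raises(ValueError):
            replicate_poverty_stats(m, LINE, reps=0)


class TestCalibrateMean:
    def test_recovers_mean_on_grid_exactly(self):
        gini, m_star = 0.43, 1500.0
        model = make_income_model(m_star, gini)
        grid = list(candidate_grid(m_star))  # contains m_star (factor 1.0)
        res = calibrate_mean(
            poverty_headcount(model, LINE), poverty_gap(model, LINE),
            LINE, gini, grid,
        )
        assert res.chosen_mean == pytest.approx(m_star, rel=1e-12)
        assert res.residual == pytest.approx(0.0, abs=1e-12)

    def test_selects_grid_neighbor_when_truth_off_grid(self):
        gini = 0.38
        grid = np.array([500.0, 800.0, 1200.0, 2000.0, 3000.0])
        m_star = 1000.0
        model = make_income_model(m_star, gini)
        obs_hc = poverty_headcount(model, LINE)
        res = calibrate_mean(obs_hc, None, LINE, gini, grid)
        # exhaustive oracle: evaluate every candidate independently
        errs = [
            abs(poverty_headcount(make_income_model(c, gini), LINE) - obs_hc)
            for c in grid
        ]
        assert res.chosen_mean == grid[int(np.argmin(errs))]
        assert res.chosen_mean in (800.0, 1200.0)

    def test_zero_headcount_selects_largest_candidate(self):
        grid = [400.0, 900.0, 5000.0]
        res = calibrate_mean(0.0, None, LINE, 0.4, grid)
        assert res.chosen_mean == 5000.0

    def test_ties_break_toward_larger_mean(self):
        # duplicate candidates produce identical errors; larger mean wins
        res = calibrate_mean(0.2, None, LINE, 0.4, [1000.0, 1000.0 + 0.0, 999.9999999])
        assert res.chosen_mean == 1000.0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            calibrate_mean(0.1, 0.05, LINE, 0.4, [])

    def test_recovery_across_many_synthetic_targets(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            gini = rng.uniform(0.28, 0.55)
            m_star = rng.uniform(400, 20000)
            model = make_income_model(m_star, gini)
            grid = candidate_grid(m_star)
            res = calibrate_mean(
                poverty_headcount(model, LINE), poverty_gap(model, GAP_LINE),
                LINE, gini, grid, gap_line=GAP_LINE,
            )
            assert res.chosen_mean == pytest.approx(m_star, rel=1e-12)


class TestChooseProxy:
    def test_hepc_generated_stats_select_hepc(self, tiny_countries):
        rec = tiny_countries[0]
        model = make_income_model(rec.hepc, rec.gini)
        rec = dataclasses.replace(
            rec,
            pov_headcount_190=poverty_headcount(model, LINE),
            pov_gap_215=poverty_gap(model, GAP_LINE),
        )
        res = choose_proxy(rec)
        assert res.proxy == "hepc"
        assert res.chosen_mean == pytest.approx(rec.hepc, rel=1e-12)
        assert res.residual == pytest.approx(0.0, abs=1e-12)

    def test_gdp_generated_stats_select_gdp(self, tiny_countries):
        rec = tiny_countries[0]
        true_mean = 0.6 * rec.gdp_pc  # inside the gdp grid, outside hepc's best
        model = make_income_model(true_mean, rec.gini)
        rec = dataclasses.replace(
            rec,
            hepc=true_mean / 10,  # hepc grid [0.25, 4] x hepc cannot reach truth
            pov_headcount_190=poverty_headcount(model, LINE),
            pov_gap_215=poverty_gap(model, GAP_LINE),
        )
        results = calibrate_proxies(rec)
        selected = next(r for r in results if r.selected)
        rejected = next(r for r in results if not r.selected)
        assert selected.proxy == "gdp_pc"
        assert selected.residual <= rejected.residual

    def test_selected_residual_never_exceeds_rejected(self, synthetic_set):
        for rec in synthetic_set.countries[:10]:
            results = calibrate_proxies(rec)
            selected = [r for r in results if r.selected]
            assert len(selected) == 1
            assert all(selected[0].residual <= r.residual for r in results)

    def test_tie_selects_hepc(self, tiny_countries):
        rec = dataclasses.replace(tiny_countries[0], gdp_pc=tiny_countries[0].hepc)
        res = choose_proxy(rec)  # identical grids -> identical residuals
        assert res.proxy == "hepc"

    def test_missing_gap_falls_back_to_headcount_only(self, tiny_countries, caplog):
        rec = dataclasses.replace(tiny_countries[0], pov_gap_215=None)
        with caplog.at_level("WARNING", logger="cherisk.calibrate"):
            res = choose_proxy(rec)
        assert res.observed_gap is None
        assert any("poverty gap missing" in r.message for r in caplog.records)

    def test_both_proxies_missing_errors(self, tiny_countries):
        rec = dataclasses.replace(tiny_countries[0], hepc=0.0, gdp_pc=None)
        with pytest.raises(ValueError, match="neither"):
            choose_proxy(rec)

    def test_grid_config_validation(self):
        with pytest.raises(ValueError):
            GridConfig(n_candidates=0)
        with pytest.raises(ValueError):
            GridConfig(lo_factor=2.0, hi_factor=1.0)
        with pytest.raises(ValueError):
            candidate_grid(-1.0)
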