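"""Experiment-layer tests: sampling, ensembles, tornado, contour, descent."""

import numpy as np
import pandas as pd
import pytest

import socioclim as sc
from socioclim.config import ParameterDistribution
from socioclim.experiments import (
    contour_grid,
    horizon_sweep,
    run_ensemble,
    sample_triangular,
    scenario_presets,
    steepest_descent_path,
    tornado,
)


@pytest.fixture(scope="module")
def short_config(baseline_config):
    """Baseline config with a 2100 horizon to keep experiment tests quick."""
    return baseline_config.replace(horizon_end=2100.0)


@pytest.fixture(scope="module")
def small_dists():
    return {
        "kappa": ParameterDistribution("kappa", 0.02, 0.05, 0.2),
        "fmax": ParameterDistribution("fmax", 4.0, 5.0, 6.0),
    }


class TestTriangularSampling:
    def test_degenerate_distribution(self):
        d = ParameterDistribution("p", 2.0, 2.0, 2.0)
        rng = np.random.default_rng(0)
        assert all(sample_triangular(d, rng) == 2.0 for _ in range(10))

    def test_moments_match_closed_form(self):
        lo, mode, hi = 1.0, 3.0, 8.0
        d = ParameterDistribution("p", lo, mode, hi)
        rng = np.random.default_rng(123)
        draws = np.array([sample_triangular(d, rng) for _ in range(100_000)])
        mean = (lo + mode + hi) / 3.0
        var = (lo**2 + mode**2 + hi**2 - lo * mode - lo * hi - mode * hi) / 18.0
        se = np.sqrt(var / draws.size)
        assert abs(draws.mean() - mean) < 3 * se
        assert draws.min() >= lo and draws.max() <= hi

    def test_cdf_at_mode_matches_closed_form(self):
        lo, mode, hi = 1.0, 3.0, 8.0
        d = ParameterDistribution("p", lo, mode, hi)
        rng = np.random.default_rng(321)
        draws = np.array([sample_triangular(d, rng) for _ in range(100_000)])
        p_mode = (mode - lo) / (hi - lo)
        se = np.sqrt(p_mode * (1 - p_mode) / draws.size)
        assert abs((draws <= mode).mean() - p_mode) < 3 * se

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterDistribution("p", 3.0, 2.0, 8.0)


class TestEnsemble:
    def test_degenerate_ensemble_equals_single_run(self, short_config):
        dists = {"kappa": ParameterDistribution("kappa", 0.05, 0.05, 0.05)}
        res = run_ensemble(short_config, dists, n=1, master_seed=1)
        traj = sc.run_coupled(short_config)
        years = res.years
        assert np.allclose(res.values["T"][0], [traj.T(y) for y in years], atol=1e-9)
        assert res.peak_anomalies[0] == pytest.approx(sc.peak_anomaly(traj), abs=1e-9)

    def test_reproducible_under_master_seed(self, short_config, small_dists):
        a = run_ensemble(short_config, small_dists, n=3, master_seed=7)
        b = run_ensemble(short_config, small_dists, n=3, master_seed=7)
        assert np.array_equal(a.values["T"], b.values["T"])
        pd.testing.assert_frame_equal(a.parameters, b.parameters)
        c = run_ensemble(short_config, small_dists, n=3, master_seed=8)
        assert not np.allclose(a.values["T"], c.values["T"])

    def test_median_is_order_statistic(self, short_config, small_dists):
        res = run_ensemble(short_config, small_dists, n=3, master_seed=11)
        probe = np.searchsorted(res.years, 2060.0)
        column = np.sort(res.values["T"][:, probe])
        assert res.median("T")[probe] == pytest.approx(column[1])

    def test_band_contains_median(self, short_config, small_dists):
        res = run_ensemble(short_config, small_dists, n=5, master_seed=3)
        lo, hi = res.band("T")
        med = res.median("T")
        assert np.all(lo <= med + 1e-12) and np.all(med <= hi + 1e-12)

    def test_overrides_bypass_sampling(self, short_config, small_dists):
        res = run_ensemble(
            short_config, small_dists, overrides={"kappa": 0.1}, n=2, master_seed=5
        )
        assert np.all(res.parameters["kappa"] == 0.1)

    def test_unknown_override_rejected(self, short_config, small_dists):
        with pytest.raises(KeyError):
            run_ensemble(short_config, small_dists, overrides={"bogus": 1.0}, n=1)


class TestTornado:
    def test_deviations_match_manual_runs(self, short_config):
        dists = {
            "beta": ParameterDistribution("beta", 0.5, 1.0, 1.5),
            "x0": ParameterDistribution("x0", 0.05, 0.05, 0.05),  # degenerate
        }
        df = tornado(short_config, dists).set_index("parameter")
        base = sc.peak_anomaly(sc.run_coupled(short_config))
        lo = sc.peak_anomaly(sc.run_coupled(sc.apply_overrides(short_config, {"beta": 0.5})))
        hi = sc.peak_anomaly(sc.run_coupled(sc.apply_overrides(short_config, {"beta": 1.5})))
        assert df.loc["beta", "dev_lower"] == pytest.approx(lo - base, abs=1e-9)
        assert df.loc["beta", "dev_upper"] == pytest.approx(hi - base, abs=1e-9)
        # degenerate parameter contributes exactly zero, and the two bounds
        # are reported separately so asymmetry is representable
        assert df.loc["x0", "dev_lower"] == 0.0 and df.loc["x0", "dev_upper"] == 0.0
        assert {"dev_lower", "dev_upper"} <= set(df.columns)

    def test_ordered_by_impact(self, short_config):
        dists = {
            "beta": ParameterDistribution("beta", 0.5, 1.0, 1.5),
            "x0": ParameterDistribution("x0", 0.05, 0.05, 0.05),
        }
        df = tornado(short_config, dists)
        impacts = df[["dev_lower", "dev_upper"]].abs().max(axis=1).to_numpy()
        assert np.all(np.diff(impacts) <= 1e-12)


class TestContourAndDescent:
    def test_single_node_equals_single_run(self, short_config):
        grid = contour_grid(short_config, beta_grid=[1.0], kappa_grid=[0.05])
        traj = sc.run_coupled(short_config)
        assert grid.shape == (1, 1)
        assert grid[0, 0] == pytest.approx(sc.peak_anomaly(traj), abs=1e-9)

    def test_peak_non_increasing_in_kappa(self, baseline_config):
        # needs the full horizon: the slow-learning peak falls after 2100
        grid = contour_grid(
            baseline_config, beta_grid=[1.0], kappa_grid=[0.02, 0.05, 0.2]
        )
        assert np.all(np.diff(grid[:, 0]) <= 1e-9)

    def test_quadratic_bowl_descends_to_analytic_minimum(self):
        beta_grid = np.linspace(0.0, 2.0, 21)
        kappa_grid = np.linspace(0.0, 0.4, 21)
        B, K = np.meshgrid(beta_grid, kappa_grid)
        surface = (B - 1.2) ** 2 + 25.0 * (K - 0.1) ** 2
        path = steepest_descent_path(
            surface, beta_grid, kappa_grid, start=(0.2, 0.35), step=0.01
        )
        assert path[-1, 0] == pytest.approx(1.2, abs=0.05)
        assert path[-1, 1] == pytest.approx(0.1, abs=0.01)

    def test_path_matches_greedy_descent_on_refined_grid(self):
        beta_grid = np.linspace(0.0, 2.0, 21)
        kappa_grid = np.linspace(0.0, 0.4, 21)
        B, K = np.meshgrid(beta_grid, kappa_grid)
        surface = (B - 1.0) ** 2 + 16.0 * (K - 0.2) ** 2
        path = steepest_descent_path(
            surface, beta_grid, kappa_grid, start=(1.8, 0.05), step=0.01
        )
        # brute-force greedy descent over a 10x refined grid
        fb = np.linspace(0.0, 2.0, 201)
        fk = np.linspace(0.0, 0.4, 201)
        bi, ki = np.argmin(np.abs(fb - 1.8)), np.argmin(np.abs(fk - 0.05))
        f = lambda i, j: (fb[j] - 1.0) ** 2 + 16.0 * (fk[i] - 0.2) ** 2
        for _ in range(2000):
            best = min(
                ((i, j) for i in range(max(ki - 1, 0), min(ki + 2, 201))
                 for j in range(max(bi - 1, 0), min(bi + 2, 201))),
                key=lambda ij: f(*ij),
            )
            if best == (ki, bi):
                break
            ki, bi = best
        cell = max(beta_grid[1] - beta_grid[0], 1.0)  # one coarse cell, beta units
        assert abs(path[-1, 0] - fb[bi]) < beta_grid[1] - beta_grid[0]
        assert abs(path[-1, 1] - fk[ki]) < kappa_grid[1] - kappa_grid[0]

    def test_start_outside_hull_rejected(self):
        grid = np.zeros((3, 3))
        with pytest.raises(ValueError):
            steepest_descent_path(grid, [0, 1, 2], [0, 1, 2], start=(5.0, 0.5))


class TestHorizonSweep:
    def test_single_value_reduces_to_ensemble(self, short_config, small_dists):
        df = horizon_sweep(short_config, small_dists, [25.0], n=2, master_seed=9)
        res = run_ensemble(
            short_config, small_dists, overrides={"tf": 25.0}, n=2, master_seed=9
        )
        assert np.allclose(np.sort(df["peak_anomaly"]), np.sort(res.peak_anomalies))

    def test_quantiles_match_independent_routine(self, short_config, small_dists):
        df = horizon_sweep(short_config, small_dists, [15.0], n=4, master_seed=2)
        vals = df["peak_anomaly"].to_numpy()
        q1, q3 = np.percentile(vals, [25, 75])
        assert q3 >= q1
        assert df["peak_anomaly"].quantile(0.75) == pytest.approx(q3)


class TestPresets:
    def test_printed_override_sets(self):
        assert scenario_presets("worst") == {
            "kappa": 0.02, "beta": 1.5, "delta": 1.5, "fmax": 4.0, "x0": 0.01
        }
        assert scenario_presets("best") == {
            "kappa": 0.2, "beta": 0.5, "delta": 0.5, "fmax": 6.0, "tf": 50.0
        }

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            scenario_presets("middling")
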