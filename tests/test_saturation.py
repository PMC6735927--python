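"""Saturation-curve fitting, nested F-tests and bootstrap bands."""

import numpy as np
import pandas as pd
import pytest

from helpers import grid_search_fit, sim_curve_points
from dupdiverge import saturation
from dupdiverge.saturation import (
    compare_partitions,
    confidence_band,
    fit_saturation,
    michaelis_menten,
    run_figure_suite,
)


class TestFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0.1, 5, 50)
        y = michaelis_menten(x, 0.4, 0.8)
        fit = fit_saturation(x, y, a_max=1.0)
        assert fit.a == pytest.approx(0.4, abs=1e-6)
        assert fit.b == pytest.approx(0.8, abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_response_degenerate(self):
        x = np.linspace(0.1, 5, 10)
        fit = fit_saturation(x, np.zeros(10))
        assert fit.a == 0.0 and fit.sse == 0.0 and not fit.b_identified

    def test_curve_through_origin_and_monotone(self):
        fit = fit_saturation(*sim_curve_points(200, 0.5, 1.0, 0.05, np.random.default_rng(0)), a_max=1.0)
        assert fit.predict(np.array([0.0]))[0] == 0.0
        grid = fit.predict(np.linspace(0, 10, 100))
        assert (np.diff(grid) >= -1e-15).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x, y = sim_curve_points(100, 0.3, 0.7, 0.1, rng)
        perm = rng.permutation(100)
        f1 = fit_saturation(x, y, a_max=1.0)
        f2 = fit_saturation(x[perm], y[perm], a_max=1.0)
        assert f1.a == pytest.approx(f2.a, abs=1e-6)
        assert f1.b == pytest.approx(f2.b, abs=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_saturation([1.0, 2.0], [0.1, 0.2])
        with pytest.raises(ValueError, match="x > 0"):
            fit_saturation([0.0, 1.0, 2.0], [0.0, 0.1, 0.2])

    def test_matches_grid_search_oracle(self):
        # Instances drawn with the half-saturation well inside the x range,
        # where both parameters are identifiable at the grid's resolution.
        rng = np.random.default_rng(7)
        for _ in range(3):
            a, b = rng.uniform(0.2, 0.9), rng.uniform(0.1, 1.0)
            x, y = sim_curve_points(200, a, b, 0.05, rng)
            fit = fit_saturation(x, y, a_max=1.0)
            ga, gb, gsse = grid_search_fit(x, y)
            assert fit.sse <= gsse + 1e-9  # optimizer at least as good as grid
            assert abs(fit.a - ga) <= 1.5e-3
            assert abs(fit.b - gb) <= 1.5e-3


class TestComparison:
    def test_identical_partitions_null(self):
        x, y = sim_curve_points(200, 0.4, 0.8, 0.05, np.random.default_rng(2))
        cmp_res = compare_partitions({"p1": (x, y), "p2": (x, y)}, a_max=1.0)
        f1, f2 = cmp_res.fits.values()
        assert f1.a == pytest.approx(f2.a, abs=1e-9)
        assert cmp_res.f_stat == pytest.approx(0.0, abs=1e-6)
        assert cmp_res.p_value > 0.999

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(3)
        parts = {
            "p1": sim_curve_points(40, 0.3, 0.5, 0.1, rng),
            "p2": sim_curve_points(60, 0.5, 0.5, 0.1, rng),
        }
        cmp_res = compare_partitions(parts, a_max=1.0)
        assert cmp_res.df_num == 2
        assert cmp_res.df_den == 100 - 4

    def test_nesting_invariant_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            parts = {
                "p1": sim_curve_points(int(rng.integers(10, 80)),
                                       rng.uniform(0.1, 0.9), rng.uniform(0.2, 1.5),
                                       0.1, rng),
                "p2": sim_curve_points(int(rng.integers(10, 80)),
                                       rng.uniform(0.1, 0.9), rng.uniform(0.2, 1.5),
                                       0.1, rng),
            }
            cmp_res = compare_partitions(parts, a_max=1.0)
            assert cmp_res.combined.sse >= cmp_res.sse_separate - 1e-9
            assert 0.0 <= cmp_res.p_value <= 1.0

    def test_distinct_asymptotes_detected(self):
        rng = np.random.default_rng(5)
        parts = {
            "fast": sim_curve_points(400, 0.45, 0.6, 0.1, rng),
            "slow": sim_curve_points(400, 0.2, 0.6, 0.1, rng),
        }
        cmp_res = compare_partitions(parts, a_max=1.0)
        assert cmp_res.p_value < 1e-6
        assert cmp_res.fits["fast"].a > cmp_res.fits["slow"].a

    def test_partition_below_fit_minimum_rejected(self):
        parts = {
            "p1": (np.array([1.0, 2.0]), np.array([0.1, 0.2])),
            "p2": (np.array([1.0, 2.0]), np.array([0.1, 0.15])),
        }
        with pytest.raises(ValueError, match="at least 3"):
            compare_partitions(parts, a_max=1.0)


class TestConfidenceBand:
    def test_band_contains_point_estimate_and_narrows_with_noise(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0.1, 5, 120)
        grid = np.linspace(0.2, 4.5, 10)
        widths = []
        for noise in (0.15, 0.01):
            y = michaelis_menten(x, 0.4, 0.8) + rng.normal(0, noise, x.size)
            fit = fit_saturation(x, y, a_max=1.0)
            band = confidence_band(x, y, fit, n_boot=120, seed=0, x_grid=grid, a_max=1.0)
            yhat = fit.predict(grid)
            assert (band.lower <= yhat + 1e-12).all()
            assert (band.upper >= yhat - 1e-12).all()
            widths.append(float(np.mean(band.upper - band.lower)))
        assert widths[1] < widths[0]

    def test_too_few_refits_error(self):
        x, y = sim_curve_points(50, 0.4, 0.8, 0.1, np.random.default_rng(7))
        fit = fit_saturation(x, y, a_max=1.0)
        with pytest.raises(RuntimeError, match="< 50"):
            confidence_band(x, y, fit, n_boot=20, seed=0, a_max=1.0)

    def test_reproducible_under_seed(self):
        x, y = sim_curve_points(80, 0.4, 0.8, 0.1, np.random.default_rng(8))
        fit = fit_saturation(x, y, a_max=1.0)
        b1 = confidence_band(x, y, fit, n_boot=100, seed=3, a_max=1.0)
        b2 = confidence_band(x, y, fit, n_boot=100, seed=3, a_max=1.0)
        assert np.array_equal(b1.lower, b2.lower)
        assert np.array_equal(b1.upper, b2.upper)


class TestFigureSuite:
    def _records(self, rng, n=120, tandem_a=0.5, block_a=0.25):
        rows = []
        for mode, a in (("tandem", tandem_a), ("block", block_a)):
            x, y = sim_curve_points(n, a, 0.8, 0.08, rng)
            for xi, yi in zip(x, y):
                rows.append(dict(mode=mode, ks=xi, ed=np.clip(yi, 0, 1),
                                 sd=np.clip(yi * 1.5, 0, None),
                                 with_ppi=bool(rng.random() < 0.5)))
        return pd.DataFrame(rows)

    def test_mode_scheme_orders_asymptotes(self):
        res = run_figure_suite(
            self._records(np.random.default_rng(9)), measures=("ed",), scheme="mode"
        )
        fits = res.fits.set_index("partition")
        assert fits.loc["tandem", "a"] > fits.loc["block", "a"]
        assert len(res.comparisons) == 1
        assert res.comparisons["p"].iloc[0] < 0.01

    def test_mode_x_ppi_compares_within_mode(self):
        res = run_figure_suite(
            self._records(np.random.default_rng(10)), measures=("ed",),
            scheme="mode_x_ppi",
        )
        assert set(res.comparisons["group"]) == {"tandem", "block"}
        assert len(res.fits) == 4

    def test_small_partition_skipped_with_report(self):
        df = self._records(np.random.default_rng(11), n=30)
        df.loc[df["mode"] == "block", "mode"] = "tandem"
        df.loc[df.index[:3], "mode"] = "block"  # 3 block rows < minimum 10
        res = run_figure_suite(df, measures=("ed",), scheme="mode")
        assert len(res.skipped) == 1
        assert res.skipped.iloc[0]["partition"] == "block"
        # single usable partition: fit emitted, comparison skipped
        assert len(res.comparisons) == 0
        assert len(res.fits) == 1
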