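"""Trend estimation, detrending, partial correlation and regional aggregation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from peatvpd import gridstats
from peatvpd.exceptions import (AlignmentError, EmptyRegionError,
                                InvalidInputError, SingularDesignError)


def _cube(arr, years=None):
    arr = np.asarray(arr, float)
    t, ny, nx = arr.shape
    years = years if years is not None else np.arange(2000, 2000 + t)
    return xr.DataArray(arr, dims=("time", "lat", "lon"),
                        coords={"time": years, "lat": np.arange(ny, dtype=float),
                                "lon": np.arange(nx, dtype=float)})


class TestOlsTrend:
    def test_exact_line(self):
        t = np.arange(10, dtype=float)
        res = gridstats.ols_trend(2 * t + 5, t)
        assert res.beta1 == pytest.approx(2.0, abs=1e-12)
        assert res.beta0 == pytest.approx(5.0, abs=1e-12)
        assert res.p_value < 1e-10
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_series(self):
        res = gridstats.ols_trend(np.full(8, 3.0))
        assert res.beta1 == 0.0
        assert res.adj_r2 <= 0.0

    def test_matches_normal_equations(self, rng):
        t = np.arange(25, dtype=float)
        y = rng.standard_normal(25)
        X = np.column_stack([np.ones(25), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        res = gridstats.ols_trend(y, t)
        assert res.beta0 == pytest.approx(beta[0], abs=1e-12)
        assert res.beta1 == pytest.approx(beta[1], abs=1e-12)

    def test_errors(self):
        with pytest.raises(SingularDesignError):
            gridstats.ols_trend(np.arange(5.0), np.full(5, 2.0))
        with pytest.raises(InvalidInputError):
            gridstats.ols_trend(np.array([1.0, 2.0]))


class TestDetrend:
    def test_linear_maps_to_zero(self):
        t = np.arange(12, dtype=float)
        assert np.allclose(gridstats.detrend(3 * t + 1, t), 0.0, atol=1e-10)

    def test_mean_zero_and_idempotent(self, rng):
        y = rng.standard_normal(30)
        d = gridstats.detrend(y)
        assert abs(d.mean()) < 1e-12
        assert np.allclose(gridstats.detrend(d), d, atol=1e-10)


class TestPartialCorrelation:
    def test_no_covariates_is_pearson(self, rng):
        from scipy import stats
        y, x = rng.standard_normal(40), rng.standard_normal(40)
        res = gridstats.partial_correlation(y, x)
        r, p = stats.pearsonr(y, x)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.df == 38

    def test_matches_residual_brute_force(self, rng):
        """Two-stage residual-correlation oracle built from polyfit residuals."""
        from scipy import stats
        for _ in range(25):
            n, g = 20, int(rng.integers(1, 5))
            y, x = rng.standard_normal(n), rng.standard_normal(n)
            Z = rng.standard_normal((n, g))
            res = gridstats.partial_correlation(y, x, list(Z.T))
            X = np.column_stack([np.ones(n), Z])
            ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
            assert res.r == pytest.approx(stats.pearsonr(ry, rx)[0], abs=1e-12)

    def test_matches_pingouin(self, rng):
        """Independent library cross-check on r and p."""
        import pingouin as pg
        for _ in range(10):
            n, g = int(rng.integers(15, 40)), int(rng.integers(1, 5))
            y, x = rng.standard_normal(n), rng.standard_normal(n)
            Z = rng.standard_normal((n, g))
            res = gridstats.partial_correlation(y, x, list(Z.T))
            df = pd.DataFrame(np.column_stack([y, x, Z]),
                              columns=["y", "x"] + [f"z{j}" for j in range(g)])
            ref = pg.partial_corr(df, "y", "x", covar=[f"z{j}" for j in range(g)])
            assert res.r == pytest.approx(ref["r"].iloc[0], abs=1e-12)
            assert res.p_value == pytest.approx(ref["p_val"].iloc[0], abs=1e-10)

    def test_shared_driver_vanishes(self, rng):
        z = rng.standard_normal(10_000)
        y = z + rng.standard_normal(10_000)
        x = z + rng.standard_normal(10_000)
        res = gridstats.partial_correlation(y, x, [z])
        assert abs(res.r) < 0.1

    def test_collinear_covariates_rejected(self, rng):
        y, x, z = (rng.standard_normal(20) for _ in range(3))
        with pytest.raises(SingularDesignError):
            gridstats.partial_correlation(y, x, [z, 2 * z])

    def test_zero_variance_residual_missing(self, rng):
        z = rng.standard_normal(20)
        res = gridstats.partial_correlation(3 * z, rng.standard_normal(20), [z])
        assert np.isnan(res.r)

    def test_insufficient_df_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            gridstats.partial_correlation(rng.standard_normal(5),
                                          rng.standard_normal(5),
                                          list(rng.standard_normal((5, 4)).T))


class TestPcorMap:
    def test_single_pixel_reduces_to_partial_correlation(self, rng):
        T = 30
        data = rng.standard_normal((4, T))
        cubes = [_cube(d.reshape(T, 1, 1)) for d in data]
        ds = gridstats.pcor_map(cubes[0], cubes[1], cubes[2:], dim="time")
        t = np.arange(2000, 2000 + T, dtype=float)
        series = [gridstats.detrend(d, t) for d in data]
        ref = gridstats.partial_correlation(series[0], series[1], series[2:])
        assert float(ds["r"][0, 0]) == pytest.approx(ref.r, abs=1e-12)
        assert float(ds["p"][0, 0]) == pytest.approx(ref.p_value, abs=1e-12)

    def test_grid_mismatch_rejected(self, rng):
        a = _cube(rng.standard_normal((10, 2, 2)))
        b = _cube(rng.standard_normal((10, 3, 2)))
        with pytest.raises(AlignmentError):
            gridstats.pcor_map(a, b, [a, a, a, a])

    def test_sparse_pixels_masked(self, rng):
        arr = rng.standard_normal((20, 1, 2))
        arr[5:, 0, 0] = np.nan      # only 25% valid
        gpp = _cube(arr)
        others = [_cube(rng.standard_normal((20, 1, 2))) for _ in range(3)]
        ds = gridstats.pcor_map(gpp, others[0], others[1:], dim="time")
        assert np.isnan(float(ds["r"][0, 0]))
        assert np.isfinite(float(ds["r"][0, 1]))

    def test_detrending_removes_cotrend_inflation(self, rng):
        """Strong shared trends inflate the raw correlation; detrending
        restores the (near-null) planted association."""
        T = 37
        t = np.arange(T, dtype=float)
        shape = (T, 6, 6)
        trend = 0.5 * t[:, None, None]
        gpp = _cube(10 + 3 * trend + rng.standard_normal(shape))
        vpd = _cube(5 + 2 * trend + rng.standard_normal(shape))
        covs = [_cube(rng.standard_normal(shape)) for _ in range(4)]
        raw = gridstats.pcor_map(gpp, vpd, covs, detrend_series=False)
        det = gridstats.pcor_map(gpp, vpd, covs, detrend_series=True)
        assert float(np.nanmean(raw["r"])) > 0.8
        assert abs(float(np.nanmean(det["r"]))) < 0.15


class TestRegionSummary:
    def _map(self, r, p):
        r, p = np.asarray(r, float), np.asarray(p, float)
        return xr.Dataset({"r": (("lat", "lon"), r), "p": (("lat", "lon"), p)},
                          coords={"lat": np.arange(r.shape[0], dtype=float),
                                  "lon": np.arange(r.shape[1], dtype=float)})

    def test_uniform_significant_positive(self):
        s = gridstats.region_summary(self._map(np.full((2, 2), 0.5),
                                               np.full((2, 2), 0.01)))
        assert s.pct_sig_pos == 100.0
        assert s.pct_sig_neg == s.pct_neg == s.pct_pos == 0.0

    def test_hand_built_enumeration(self):
        r = [[-0.5, -0.1], [0.3, 0.7]]
        p = [[0.01, 0.5], [0.2, 0.001]]
        s = gridstats.region_summary(self._map(r, p))
        assert (s.pct_sig_neg, s.pct_neg, s.pct_pos, s.pct_sig_pos) == (25, 25, 25, 25)
        assert s.mean_r == pytest.approx(0.1)

    def test_mean_of_opposites_is_zero(self):
        s = gridstats.region_summary(self._map([[-0.2, 0.2]], [[0.5, 0.5]]))
        assert s.mean_r == pytest.approx(0.0)

    def test_percentages_partition(self, rng):
        r = rng.uniform(-1, 1, (10, 10))
        p = rng.uniform(0, 1, (10, 10))
        s = gridstats.region_summary(self._map(r, p))
        assert s.pct_sig_neg + s.pct_neg + s.pct_sig_pos + s.pct_pos == pytest.approx(
            100.0, abs=1e-9)

    def test_empty_region_rejected(self):
        with pytest.raises(EmptyRegionError):
            gridstats.region_summary(self._map([[0.1]], [[0.5]]),
                                     mask=np.array([[False]]))

    def test_extent_bins_enumeration(self):
        r = np.array([[0.1, 0.2, -0.3, 0.4, 0.5, 0.6]])
        p = np.full((1, 6), 0.5)
        extent = np.array([[5.0, 10.0, 19.9, 20.0, 70.0, 100.0]])
        out = gridstats.extent_gradient(self._map(r, p), extent)
        by_label = {s.label: s for s in out}
        assert by_label["[10,20)"].n_pixels == 2          # 10.0 and 19.9
        assert by_label["[20,30)"].n_pixels == 1
        assert by_label[">70"].n_pixels == 2              # 70 and 100
        assert by_label[">=10"].n_pixels == 5
        assert by_label["[30,40)"].n_pixels == 0

    def test_uniform_extent_single_bin(self):
        r = np.full((2, 3), 0.2)
        p = np.full((2, 3), 0.5)
        out = gridstats.extent_gradient(self._map(r, p), np.full((2, 3), 50.0))
        populated = [s for s in out if s.n_pixels > 0 and s.label != ">=10"]
        assert len(populated) == 1 and populated[0].label == "[50,60)"


class TestAriditySplit:
    def test_boundary(self):
        masks = gridstats.aridity_split(np.array([0.65, 0.64999, 2.0, 0.0]))
        assert masks["humid_mask"].tolist() == [True, False, True, False]
        assert masks["nonhumid_mask"].tolist() == [False, True, False, True]

    def test_partition(self, rng):
        ai = rng.uniform(0, 3, 100)
        masks = gridstats.aridity_split(ai)
        assert not np.any(masks["humid_mask"] & masks["nonhumid_mask"])
        assert np.all(masks["humid_mask"] | masks["nonhumid_mask"])


class TestTowerGridAgreement:
    def test_identical(self, rng):
        rs = list(rng.uniform(-1, 1, 10))
        out = gridstats.tower_grid_agreement(rs, rs)
        assert out["sign_agreement_pct"] == 100.0
        assert out["r"] == pytest.approx(1.0)

    def test_opposite(self, rng):
        rs = rng.uniform(0.1, 1, 8)
        out = gridstats.tower_grid_agreement(list(rs), list(-rs))
        assert out["sign_agreement_pct"] == 0.0

    def test_hand_count(self):
        out = gridstats.tower_grid_agreement([0.5, -0.2, 0.1, -0.9],
                                             [0.3, 0.4, -0.2, -0.5])
        assert out["sign_agreement_pct"] == 50.0

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            gridstats.tower_grid_agreement([0.1], [0.1, 0.2])


class TestAnnualAggregation:
    def test_growing_season_annual_means(self):
        times = pd.date_range("2000-01-01", periods=36, freq="MS")
        ta_month = np.where(np.isin(times.month, [6, 7, 8]), 10.0, -5.0)
        ta = xr.DataArray(np.tile(ta_month[:, None, None], (1, 1, 1)),
                          dims=("time", "lat", "lon"),
                          coords={"time": times, "lat": [0.0], "lon": [0.0]})
        vals = np.arange(36, dtype=float)[:, None, None]
        cube = xr.DataArray(vals, dims=("time", "lat", "lon"), coords=ta.coords)
        out = gridstats.annual_growing_season_mean(cube, ta)
        # year 2000: months Jun-Aug are indices 5, 6, 7
        assert float(out.sel(year=2000)[0, 0]) == pytest.approx(np.mean([5, 6, 7]))
        assert out.sizes["year"] == 3
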