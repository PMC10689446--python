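"""Per-pixel trend estimation, detrending and partial-correlation mapping.

The central statistic is the partial correlation (PCOR) between detrended
annual growing-season GPP and detrended VPD, conditional on four detrended
covariates (air temperature, radiation, wind speed, precipitation), computed
independently for every grid pixel.  Regional aggregation reports the mean
coefficient and the percentage of pixels in each sign x significance class,
optionally stratified by peatland-extent bin or aridity class.

Temporal unit: annual growing-season means per pixel (so the sample size per
pixel is the number of years); a monthly-anomaly mode is available upstream
by passing monthly cubes directly.  Significance is a two-sided t test with
df = n - 2 - g and no multiple-testing correction across pixels (raw p < 0.05
maps are the convention reproduced here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .exceptions import (AlignmentError, DegenerateInputError, EmptyRegionError,
                         InvalidInputError, SingularDesignError)

__all__ = [
    "TrendResult", "PcorResult", "RegionSummary",
    "ols_trend", "detrend", "partial_correlation", "pcor_map",
    "region_summary", "extent_gradient", "aridity_split",
    "tower_grid_agreement", "annual_growing_season_mean",
    "PcorMap", "PcorMapResults",
]

EXTENT_BIN_EDGES = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)
ARIDITY_HUMID_THRESHOLD = 0.65


@dataclass(frozen=True)
class TrendResult:
    """Least-squares linear trend ``y = beta0 + beta1*t + eps``."""
    beta0: float
    beta1: float
    se_beta1: float
    p_value: float
    adj_r2: float
    n: int


@dataclass(frozen=True)
class PcorResult:
    """Partial-correlation coefficient with its t-test metadata.

    ``df = n - 2 - g`` where g is the number of covariates.
    """
    r: float
    p_value: float
    n: int
    g: int

    @property
    def df(self) -> int:
        return self.n - 2 - self.g


@dataclass(frozen=True)
class RegionSummary:
    """Regional aggregate of a partial-correlation map.

    The four percentages partition valid pixels by sign(r) x (p < alpha)
    and sum to 100 (r = 0 ties counted as positive).
    """
    mean_r: float
    pct_sig_neg: float
    pct_neg: float
    pct_sig_pos: float
    pct_pos: float
    n_pixels: int
    label: str = ""


def _validate_series(y, t=None, min_n=3):
    y = np.asarray(y, dtype=float)
    if t is None:
        t = np.arange(y.size, dtype=float)
    else:
        t = np.asarray(t, dtype=float)
    if y.size != t.size:
        raise AlignmentError("series and time axis differ in length")
    if y.size < min_n:
        raise InvalidInputError(f"need at least {min_n} observations, got {y.size}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(t))):
        raise InvalidInputError("series must be finite after masking")
    return y, t


def ols_trend(y, t=None) -> TrendResult:
    """Ordinary-least-squares linear trend with a two-sided t test on the slope."""
    y, t = _validate_series(y, t)
    if np.ptp(t) == 0:
        raise SingularDesignError("time axis is constant")
    n = y.size
    if np.ptp(y) == 0:
        # constant series: zero slope, no explanatory power
        return TrendResult(beta0=float(y[0]), beta1=0.0, se_beta1=0.0,
                           p_value=1.0, adj_r2=float(1.0 - (n - 1) / (n - 2)), n=n)
    res = stats.linregress(t, y)
    adj_r2 = 1.0 - (1.0 - res.rvalue ** 2) * (n - 1) / (n - 2)
    return TrendResult(beta0=float(res.intercept), beta1=float(res.slope),
                       se_beta1=float(res.stderr), p_value=float(res.pvalue),
                       adj_r2=float(adj_r2), n=n)


def detrend(y, t=None):
    """Residuals of the least-squares linear fit of ``y`` on time.

    Mean-zero by construction and idempotent (a projection).
    """
    y, t = _validate_series(y, t)
    if np.ptp(t) == 0:
        raise SingularDesignError("time axis is constant")
    coef = np.polyfit(t, y, 1)
    return y - np.polyval(coef, t)


def _residualize(v, Z):
    """Residuals of v on the design [1, Z] via least squares."""
    X = np.column_stack([np.ones(v.size)] + ([Z] if Z.ndim == 1 else list(Z.T)))
    beta, _, rank, _ = np.linalg.lstsq(X, v, rcond=None)
    if rank < X.shape[1]:
        raise SingularDesignError("covariates are collinear (rank-deficient design)")
    return v - X @ beta


def partial_correlation(y, x, z: Sequence = ()) -> PcorResult:
    """Partial correlation of y and x given covariates z.

    Defined (and computed) as the Pearson correlation of the residuals of the
    y-on-z and x-on-z regressions, each with an intercept.  With no
    covariates this reduces to the plain Pearson correlation.  p-value from a
    two-sided t test with df = n - 2 - g.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    zs = [np.asarray(zi, dtype=float) for zi in z]
    n = y.size
    g = len(zs)
    if x.size != n or any(zi.size != n for zi in zs):
        raise AlignmentError("all series must share the same length")
    df = n - 2 - g
    if df < 1:
        raise InvalidInputError(f"df = n - 2 - g = {df} < 1")
    if zs:
        Z = np.column_stack(zs)
        ry = _residualize(y, Z)
        rx = _residualize(x, Z)
    else:
        ry = y - y.mean()
        rx = x - x.mean()
    sy = np.sqrt(np.sum(ry ** 2))
    sx = np.sqrt(np.sum(rx ** 2))
    # residuals that vanish to numerical precision leave r undefined
    tol_y = 1e-10 * np.sqrt(np.sum((y - y.mean()) ** 2))
    tol_x = 1e-10 * np.sqrt(np.sum((x - x.mean()) ** 2))
    if sy <= tol_y or sx <= tol_x or sy == 0 or sx == 0:
        return PcorResult(r=np.nan, p_value=np.nan, n=n, g=g)
    r = float(np.clip(np.dot(ry, rx) / (sy * sx), -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t_stat = r * np.sqrt(df / (1.0 - r ** 2))
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return PcorResult(r=r, p_value=p, n=n, g=g)


def _check_grids(*cubes: xr.DataArray, dim="time"):
    ref = cubes[0]
    for c in cubes[1:]:
        if c.dims != ref.dims or c.shape != ref.shape:
            raise AlignmentError("cubes do not share dimensions/shape")
        for d in ref.dims:
            if not np.array_equal(np.asarray(c[d]), np.asarray(ref[d])):
                raise AlignmentError(f"cubes disagree on coordinate '{d}'")
    if dim not in ref.dims:
        raise AlignmentError(f"cubes lack a '{dim}' dimension")


def _normalize_lat(da: xr.DataArray) -> xr.DataArray:
    if "lat" in da.dims and da["lat"].size > 1 and float(da["lat"][0]) > float(da["lat"][-1]):
        return da.sortby("lat")
    return da


def pcor_map(gpp: xr.DataArray, vpd: xr.DataArray,
             covariates: Sequence[xr.DataArray], dim: str = "time",
             min_valid_frac: float = 0.8, detrend_series: bool = True) -> xr.Dataset:
    """Pixel-wise partial correlation of GPP vs VPD given covariates.

    Every pixel's series are (optionally, default) detrended before the
    correlation; pixels with fewer than ``min_valid_frac`` of the time steps
    jointly valid across all inputs, or with df < 1, are masked.

    Returns an ``xarray.Dataset`` with variables ``r``, ``p``, ``n`` on the
    spatial coordinates.
    """
    cubes = [gpp, vpd, *covariates]
    cubes = [_normalize_lat(c) for c in cubes]
    _check_grids(*cubes, dim=dim)
    gpp, vpd = cubes[0], cubes[1]
    covs = cubes[2:]
    g = len(covs)

    t_axis = np.asarray(gpp[dim], dtype=float) if np.issubdtype(
        np.asarray(gpp[dim]).dtype, np.number) else np.arange(gpp.sizes[dim], dtype=float)
    arrs = [np.moveaxis(np.asarray(c, dtype=float), c.dims.index(dim), 0) for c in cubes]
    T = arrs[0].shape[0]
    space_shape = arrs[0].shape[1:]
    flat = [a.reshape(T, -1) for a in arrs]
    n_pix = flat[0].shape[1]

    r_out = np.full(n_pix, np.nan)
    p_out = np.full(n_pix, np.nan)
    n_out = np.zeros(n_pix, dtype=np.int64)
    min_n = max(int(np.ceil(min_valid_frac * T)), g + 3)

    for j in range(n_pix):
        cols = [f[:, j] for f in flat]
        valid = np.all(np.isfinite(np.column_stack(cols)), axis=1)
        n = int(valid.sum())
        if n < min_n or n - 2 - g < 1:
            continue
        tt = t_axis[valid]
        series = [c[valid] for c in cols]
        if detrend_series:
            try:
                series = [detrend(s, tt) for s in series]
            except SingularDesignError:
                continue
        try:
            res = partial_correlation(series[0], series[1], series[2:])
        except SingularDesignError:
            continue
        r_out[j], p_out[j], n_out[j] = res.r, res.p_value, n

    spatial_dims = [d for d in gpp.dims if d != dim]
    coords = {d: gpp[d] for d in spatial_dims}
    ds = xr.Dataset(
        {
            "r": (spatial_dims, r_out.reshape(space_shape)),
            "p": (spatial_dims, p_out.reshape(space_shape)),
            "n": (spatial_dims, n_out.reshape(space_shape)),
        },
        coords=coords,
        attrs={"g": g, "detrended": int(detrend_series),
               "min_valid_frac": min_valid_frac},
    )
    return ds


def _extract_rp(rmap):
    if isinstance(rmap, xr.Dataset):
        return np.asarray(rmap["r"], float), np.asarray(rmap["p"], float)
    raise InvalidInputError("expected the Dataset produced by pcor_map")


def region_summary(rmap: xr.Dataset, mask=None, alpha: float = 0.05,
                   label: str = "", cos_lat_weights: bool = False) -> RegionSummary:
    """Mean r and sign x significance percentages over a masked region.

    ``cos_lat_weights=True`` weights the mean r by cos(latitude); the
    percentage partition is always an unweighted pixel count.
    """
    r, p = _extract_rp(rmap)
    valid = np.isfinite(r)
    if mask is not None:
        valid &= np.asarray(mask, bool)
    n = int(valid.sum())
    if n == 0:
        raise EmptyRegionError("no valid pixels in region")
    rv, pv = r[valid], p[valid]
    neg = rv < 0
    sig = pv < alpha
    pct = lambda m: 100.0 * float(np.sum(m)) / n
    if cos_lat_weights and "lat" in rmap.coords:
        w = np.cos(np.deg2rad(np.asarray(
            xr.broadcast(rmap["r"], rmap["lat"])[1], float)))[valid]
        mean_r = float(np.average(rv, weights=w))
    else:
        mean_r = float(np.mean(rv))
    return RegionSummary(
        mean_r=mean_r,
        pct_sig_neg=pct(neg & sig), pct_neg=pct(neg & ~sig),
        pct_sig_pos=pct(~neg & sig), pct_pos=pct(~neg & ~sig),
        n_pixels=n, label=label,
    )


def _empty_summary(label):
    return RegionSummary(mean_r=np.nan, pct_sig_neg=np.nan, pct_neg=np.nan,
                         pct_sig_pos=np.nan, pct_pos=np.nan, n_pixels=0, label=label)


def extent_gradient(rmap: xr.Dataset, extent, alpha: float = 0.05):
    """Regional summaries across peatland-extent bins.

    Bins are left-closed [10,20), [20,30), ..., [60,70) with a final closed
    bin [70,100], plus the union of all pixels with extent >= 10%.  Empty
    bins yield a zero-pixel placeholder summary rather than an error.
    """
    ext = np.asarray(extent, dtype=float)
    if np.any((ext < 0) | (ext > 100)):
        raise InvalidInputError("extent must be a percentage in [0, 100]")
    edges = list(EXTENT_BIN_EDGES)
    out = []
    for lo, hi in zip(edges, edges[1:] + [100.0]):
        last = hi == 100.0
        m = (ext >= lo) & ((ext <= hi) if last else (ext < hi))
        lab = f">{lo:.0f}" if last else f"[{lo:.0f},{hi:.0f})"
        try:
            out.append(region_summary(rmap, mask=m, alpha=alpha, label=lab))
        except EmptyRegionError:
            out.append(_empty_summary(lab))
    try:
        out.append(region_summary(rmap, mask=ext >= 10.0, alpha=alpha, label=">=10"))
    except EmptyRegionError:
        out.append(_empty_summary(">=10"))
    return out


def aridity_split(ai):
    """Humid / nonhumid masks from the aridity index (P/PET).

    Nonhumid: AI < 0.65 (strict); humid: AI >= 0.65.  The masks partition
    the valid (finite, non-negative) pixels.
    """
    ai = np.asarray(ai, dtype=float)
    if np.any(ai < 0):
        raise InvalidInputError("aridity index must be non-negative")
    valid = np.isfinite(ai)
    return {
        "nonhumid_mask": valid & (ai < ARIDITY_HUMID_THRESHOLD),
        "humid_mask": valid & (ai >= ARIDITY_HUMID_THRESHOLD),
    }


def tower_grid_agreement(tower_pcors, grid_pcors):
    """Sign agreement (%) and Pearson r between paired tower and grid PCORs."""
    def _rs(lst):
        return np.asarray([p.r if isinstance(p, PcorResult) else float(p) for p in lst])
    a, b = _rs(tower_pcors), _rs(grid_pcors)
    if a.size != b.size:
        raise AlignmentError("paired lists differ in length")
    if a.size == 0:
        raise EmptyRegionError("no pairs")
    sign = lambda v: np.where(v < 0, -1, 1)  # ties to positive
    agree = 100.0 * float(np.mean(sign(a) == sign(b)))
    if a.size >= 3 and np.std(a) > 0 and np.std(b) > 0:
        r = float(stats.pearsonr(a, b)[0])
    else:
        r = np.nan
    return {"sign_agreement_pct": agree, "r": r}


def annual_growing_season_mean(cube: xr.DataArray, ta: xr.DataArray,
                               dim: str = "time") -> xr.DataArray:
    """Aggregate monthly cubes to annual growing-season means per pixel.

    The growing season is the set of calendar months whose climatological
    mean air temperature at that pixel exceeds 0 degC; values outside it are
    excluded before the annual mean.
    """
    _check_grids(cube, ta, dim=dim)
    times = pd.DatetimeIndex(np.asarray(cube[dim]))
    month = xr.DataArray(times.month, coords={dim: cube[dim]}, dims=dim)
    clim = ta.groupby(month.rename("month")).mean(dim)
    gs = (clim > 0.0).sel(month=month).drop_vars("month")
    year = xr.DataArray(times.year, coords={dim: cube[dim]}, dims=dim)
    masked = cube.where(gs)
    return masked.groupby(year.rename("year")).mean(dim)


class PcorMap:
    """Model-style wrapper for the pixel-wise partial-correlation analysis.

    Parameters mirror :func:`pcor_map`; ``fit()`` runs the per-pixel
    detrended partial correlations and returns :class:`PcorMapResults`.
    """

    def __init__(self, gpp, vpd, covariates, dim="time",
                 min_valid_frac=0.8, detrend=True):
        self.gpp, self.vpd, self.covariates = gpp, vpd, covariates
        self.dim, self.min_valid_frac, self.detrend = dim, min_valid_frac, detrend

    def fit(self) -> "PcorMapResults":
        maps = pcor_map(self.gpp, self.vpd, self.covariates, dim=self.dim,
                        min_valid_frac=self.min_valid_frac,
                        detrend_series=self.detrend)
        return PcorMapResults(maps)


@dataclass
class PcorMapResults:
    """Fitted partial-correlation maps with regional aggregation helpers."""
    maps: xr.Dataset

    def region_summary(self, mask=None, alpha=0.05, label="", **kw) -> RegionSummary:
        return region_summary(self.maps, mask=mask, alpha=alpha, label=label, **kw)

    def extent_gradient(self, extent, alpha=0.05):
        return extent_gradient(self.maps, extent, alpha=alpha)

    def aridity_summaries(self, ai, alpha=0.05):
        masks = aridity_split(ai)
        return {k: self.region_summary(mask=v, alpha=alpha, label=k)
                for k, v in masks.items() if np.any(v)}

    def summary(self) -> str:
        s = self.region_summary(label="all")
        lines = [
            "Partial-correlation map (GPP vs VPD | Ta, radiation, wind, precipitation)",
            f"  valid pixels : {s.n_pixels}",
            f"  mean r       : {s.mean_r:+.4f}",
            f"  sig. negative: {s.pct_sig_neg:5.1f}%   negative: {s.pct_neg:5.1f}%",
            f"  sig. positive: {s.pct_sig_pos:5.1f}%   positive: {s.pct_pos:5.1f}%",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **imshow_kw):
        """Map of the partial-correlation coefficient."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        r = self.maps["r"]
        im = ax.imshow(np.asarray(r), origin="lower", cmap="RdBu",
                       vmin=-1, vmax=1, **imshow_kw)
        ax.set_xlabel("lon index")
        ax.set_ylabel("lat index")
        ax.figure.colorbar(im, ax=ax, label="partial r (GPP vs VPD)")
        return ax

    def to_netcdf(self, path):
        from .io import write_netcdf
        write_netcdf(self.maps, path)

    def summaries_to_csv(self, summaries, path):
        pd.DataFrame([vars(s) for s in summaries]).to_csv(path, index=False)
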