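"""Synthetic-data generators with machine-readable ground truth.

Every generator emulates exactly the statistical structure the analysis
modules assume — no more climatological realism than the analyses consume:

* :func:`gen_gridded` — annual growing-season climate/GPP cubes on a lat/lon
  grid with linear decadal trends, exponential Ta–VPD coupling, RH derived by
  inverting the saturation curve, mildly cross-correlated covariate
  anomalies, and a *planted* per-pixel partial correlation between detrended
  GPP and detrended VPD conditional on the four covariates.
* :func:`gen_flux_tower` — monthly tower series built from the forward
  Penman–Monteith equation at a known canopy conductance, so the inversion
  recovers it; GPP follows a configured uWUE law.
* :func:`gen_warming_sites` — a synthesis table of paired control/warming
  sites with a planted growth-response slope on the VPD increase.
* :func:`gen_rf_table` / :func:`gen_mediation_data` / :func:`gen_trait_table`
  — pixel tables with planted additive or serial-mediation structure for the
  sensitivity and mediation modules.

Each generator takes a mandatory seed (no global RNG), is bit-reproducible,
and returns its ground truth alongside the data; recovery tests read truth
only from that sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
import xarray as xr

from . import metphys
from .exceptions import InvalidInputError

__all__ = [
    "GridGenConfig", "FluxGenConfig", "SyntheticGrid",
    "gen_gridded", "gen_flux_tower", "gen_warming_sites",
    "gen_rf_table", "gen_mediation_data", "gen_trait_table",
]


@dataclass
class GridGenConfig:
    """Configuration for the gridded generator.

    ``target_pcor`` may be a scalar, a (n_lat, n_lon) array, or a callable of
    the peatland-extent field (values in %) returning per-pixel rho.
    ``extent_field`` is "uniform_random", "lon_ramp", or a constant float.
    Trend defaults match the observed high-latitude warming rate
    (0.028 degC yr-1 over 1982-2018).
    """
    n_lat: int = 10
    n_lon: int = 10
    year_start: int = 1982
    year_end: int = 2018
    ta_base_range: Tuple[float, float] = (5.0, 15.0)
    ta_trend: float = 0.028           # degC per year
    ta_noise_sd: float = 0.6          # interannual variability, degC
    vpd_a: float = 2.0                # hPa, exponential coupling scale
    vpd_b: float = 0.06               # per degC
    vpd_lognoise_sd: float = 0.08
    target_pcor: Union[float, np.ndarray, Callable] = 0.0
    ta_effect: float = 0.4            # GPP loading on Ta anomalies (per degC-sd)
    covar_effect: float = 0.3         # GPP loading on each covariate anomaly
    covar_cross_corr: float = 0.3
    gpp_base: float = 300.0           # g C m-2 per growing season
    gpp_trend: float = 0.5            # g C m-2 yr-1
    gpp_sd: float = 30.0              # structural anomaly scale
    extent_field: Union[str, float] = "uniform_random"
    ai_lognorm: Tuple[float, float] = (-0.2, 0.5)   # (mean, sd) of ln(AI)
    seed: int = 0

    def __post_init__(self):
        if self.year_end - self.year_start + 1 < 5:
            raise InvalidInputError("need at least 5 years")
        for sd in (self.ta_noise_sd, self.vpd_lognoise_sd, self.gpp_sd):
            if sd <= 0:
                raise InvalidInputError("noise sds must be positive")


@dataclass
class FluxGenConfig:
    """Configuration for the synthetic flux tower."""
    n_months: int = 120
    true_gc: float = 6.0              # mm s-1 (scalar or per-month array)
    uwue_true: float = 1.5            # g C kPa^0.5 kg-1 H2O
    ta_mean: float = 8.0
    ta_amp: float = 12.0              # seasonal amplitude, degC
    ta_noise_sd: float = 1.0
    rh_mean: float = 75.0
    rh_sd: float = 4.0
    ws_mean: float = 3.0
    ws_sd: float = 0.5
    ustar_mean: float = 0.35
    ustar_sd: float = 0.05
    h_mean: float = 60.0              # sensible heat, W m-2
    h_sd: float = 15.0
    pressure_kpa: float = 101.325
    flux_noise_sd: float = 0.0        # lognormal sd on LE, H, GPP
    seed: int = 0

    def __post_init__(self):
        if np.any(np.asarray(self.true_gc) <= 0):
            raise InvalidInputError("true_gc must be positive")


@dataclass
class SyntheticGrid:
    """Gridded synthetic dataset plus its ground truth."""
    data: xr.Dataset
    truth: pd.DataFrame          # one row per pixel: lat, lon, rho, extent, ai
    meta: Dict

    def truth_sidecar(self) -> Dict:
        return {"pixels": self.truth.to_dict(orient="list"), **self.meta}

    def write(self, directory):
        """NetCDF cubes + CSV truth table + JSON truth sidecar."""
        from pathlib import Path
        from .io import write_netcdf
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_netcdf(self.data, d / "grid.nc")
        self.truth.to_csv(d / "truth.csv", index=False)
        with open(d / "truth.json", "w") as fh:
            json.dump(self.truth_sidecar(), fh, indent=1)
        return d


def _detrend_matrix(tau: np.ndarray) -> np.ndarray:
    """Projection onto the orthogonal complement of span{1, tau}."""
    T = tau.size
    X = np.column_stack([np.ones(T), tau])
    return np.eye(T) - X @ np.linalg.solve(X.T @ X, X.T)


def gen_gridded(cfg: GridGenConfig) -> SyntheticGrid:
    """Generate annual growing-season cubes with a planted conditional correlation.

    Construction per pixel: Ta = baseline + trend*t + noise; VPD follows the
    exponential coupling a*exp(b*Ta) with multiplicative lognormal noise
    (resampled where it would exceed saturation, so the derived RH stays in
    (0, 100)); covariate anomalies share a mild cross-correlation.  The GPP
    anomaly is built from the *sample* residual of detrended VPD on the four
    detrended covariates, so the partial correlation recovered by the
    analysis has expectation rho (exactly null-distributed when rho = 0).
    """
    rng = np.random.default_rng(cfg.seed)
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    T = years.size
    NY, NX = cfg.n_lat, cfg.n_lon
    P = NY * NX
    lat = np.linspace(50.25, 69.75, NY)
    lon = np.linspace(-179.75, 179.75, NX) if NX > 1 else np.array([0.25])
    tau = (years - years.mean()).astype(float)
    t0 = years - cfg.year_start

    # static fields
    if isinstance(cfg.extent_field, str):
        if cfg.extent_field == "uniform_random":
            extent = rng.uniform(0.0, 100.0, P)
        elif cfg.extent_field == "lon_ramp":
            extent = np.tile(np.linspace(5.0, 95.0, NX), NY)
        else:
            raise InvalidInputError(f"unknown extent_field '{cfg.extent_field}'")
    else:
        extent = np.full(P, float(cfg.extent_field))
    ai = rng.lognormal(cfg.ai_lognorm[0], cfg.ai_lognorm[1], P)

    if callable(cfg.target_pcor):
        rho = np.asarray(cfg.target_pcor(extent), dtype=float)
    else:
        rho = np.broadcast_to(np.asarray(cfg.target_pcor, dtype=float).reshape(-1)
                              if np.ndim(cfg.target_pcor) else cfg.target_pcor, (P,)).copy() \
            if np.ndim(cfg.target_pcor) <= 1 else np.asarray(cfg.target_pcor, float).reshape(P)
    rho = np.broadcast_to(rho, (P,)).astype(float).copy()
    if np.any(np.abs(rho) >= 1):
        raise InvalidInputError("|target_pcor| must be < 1")

    # temperature and VPD
    ta_base = rng.uniform(*cfg.ta_base_range, P)
    ta_anom = rng.normal(0.0, cfg.ta_noise_sd, (T, P))
    ta = ta_base + cfg.ta_trend * t0[:, None] + ta_anom
    svp = metphys.svp(ta)
    eps = rng.normal(0.0, cfg.vpd_lognoise_sd, (T, P))
    vpd = cfg.vpd_a * np.exp(cfg.vpd_b * ta) * np.exp(eps)
    n_resampled = 0
    for _ in range(200):
        bad = vpd >= svp
        if not bad.any():
            break
        n_resampled += int(bad.sum())
        eps_new = rng.normal(0.0, cfg.vpd_lognoise_sd, int(bad.sum()))
        vpd[bad] = cfg.vpd_a * np.exp(cfg.vpd_b * ta[bad]) * np.exp(
            -np.abs(eps_new))  # pull toward/below the mean curve
    if (vpd >= svp).any():
        raise InvalidInputError("could not keep VPD below saturation; "
                                "lower vpd_a or vpd_lognoise_sd")
    rh = 100.0 * (1.0 - vpd / svp)
    assert np.all((rh > 0) & (rh <= 100)), "generated RH left (0, 100]"

    # covariates with mild mutual correlation
    r = cfg.covar_cross_corr
    C = np.full((3, 3), r) + (1 - r) * np.eye(3)
    L = np.linalg.cholesky(C)
    zc = rng.standard_normal((T, P, 3)) @ L.T
    radiation = 180.0 + 15.0 * zc[..., 0]
    wind = 3.0 + 0.5 * zc[..., 1]
    precip = 60.0 + 15.0 * zc[..., 2]

    # planted conditional-correlation structure
    M = _detrend_matrix(tau)
    Dv = M @ vpd
    Z = np.stack([M @ ta, M @ radiation, M @ wind, M @ precip], axis=2)  # (T,P,4)
    G = np.einsum("tpi,tpj->pij", Z, Z)
    bvec = np.einsum("tpi,tp->pi", Z, Dv)
    coef = np.linalg.solve(G, bvec[..., None])[..., 0]
    v_res = Dv - np.einsum("tpi,pi->tp", Z, coef)
    v_std = v_res / v_res.std(axis=0, ddof=1)
    # noise enters through the same detrend+residualize filter as the signal,
    # so the planted rho is the expectation of the recovered coefficient
    e = rng.standard_normal((T, P))
    De = M @ e
    be = np.einsum("tpi,tp->pi", Z, De)
    e_res = De - np.einsum("tpi,pi->tp", Z, np.linalg.solve(G, be[..., None])[..., 0])
    e_std = e_res / e_res.std(axis=0, ddof=1)
    struct = rho * v_std + np.sqrt(1.0 - rho ** 2) * e_std

    gpp = (cfg.gpp_base + cfg.gpp_trend * t0[:, None]
           + cfg.gpp_sd * struct
           + cfg.ta_effect * cfg.gpp_sd * ta_anom / cfg.ta_noise_sd
           + cfg.covar_effect * cfg.gpp_sd * zc.sum(axis=2) / np.sqrt(3.0))

    def cube(arr, units):
        return xr.DataArray(arr.reshape(T, NY, NX), dims=("year", "lat", "lon"),
                            coords={"year": years, "lat": lat, "lon": lon},
                            attrs={"units": units})

    data = xr.Dataset({
        "gpp": cube(gpp, "g C m-2"),
        "vpd": cube(vpd, "hPa"),
        "ta": cube(ta, "degC"),
        "rh": cube(rh, "%"),
        "radiation": cube(radiation, "W m-2"),
        "wind": cube(wind, "m s-1"),
        "precip": cube(precip, "mm"),
        "extent": xr.DataArray(extent.reshape(NY, NX), dims=("lat", "lon"),
                               coords={"lat": lat, "lon": lon}, attrs={"units": "%"}),
        "ai": xr.DataArray(ai.reshape(NY, NX), dims=("lat", "lon"),
                           coords={"lat": lat, "lon": lon}, attrs={"units": "1"}),
    }, attrs={"seed": cfg.seed, "title": "synthetic annual growing-season cubes"})

    glat, glon = np.meshgrid(lat, lon, indexing="ij")
    truth = pd.DataFrame({"lat": glat.ravel(), "lon": glon.ravel(),
                          "rho": rho, "extent": extent, "ai": ai})
    meta = {"seed": cfg.seed, "n_vpd_resampled": n_resampled,
            "ta_trend": cfg.ta_trend, "vpd_a": cfg.vpd_a, "vpd_b": cfg.vpd_b}
    return SyntheticGrid(data=data, truth=truth, meta=meta)


SECONDS_PER_MONTH = 30.4375 * 86400.0


def gen_flux_tower(cfg: FluxGenConfig) -> Tuple[pd.DataFrame, Dict]:
    """Monthly tower series from the forward Penman–Monteith model.

    LE is computed at the configured true canopy conductance, H is drawn
    independently, ET converts LE with the 2.44 MJ kg-1 latent heat, and GPP
    follows GPP = uWUE_true * ET / sqrt(VPD_kPa) so the uWUE computed from
    the series returns the configured value exactly (noiseless case).
    Optional multiplicative lognormal noise applies to LE, H, GPP.
    """
    rng = np.random.default_rng(cfg.seed)
    m = np.arange(cfg.n_months)
    ta = (cfg.ta_mean + cfg.ta_amp * np.sin(2 * np.pi * (m % 12 - 3) / 12.0)
          + rng.normal(0, cfg.ta_noise_sd, cfg.n_months))
    rh = np.clip(rng.normal(cfg.rh_mean, cfg.rh_sd, cfg.n_months), 30.0, 99.0)
    ws = np.clip(rng.normal(cfg.ws_mean, cfg.ws_sd, cfg.n_months), 0.5, None)
    ustar = np.clip(rng.normal(cfg.ustar_mean, cfg.ustar_sd, cfg.n_months), 0.05, None)
    h = rng.normal(cfg.h_mean, cfg.h_sd, cfg.n_months)
    vpd = metphys.vpd_from_rh(ta, rh)                     # hPa
    vpd = np.maximum(vpd, 0.05)
    gc = np.broadcast_to(np.asarray(cfg.true_gc, float), (cfg.n_months,))

    le_clean = metphys.penman_monteith_le(gc, h, vpd, ws, ustar, ta, cfg.pressure_kpa)
    if cfg.flux_noise_sd > 0:
        le = le_clean * rng.lognormal(0.0, cfg.flux_noise_sd, cfg.n_months)
        h_obs = h * rng.lognormal(0.0, cfg.flux_noise_sd, cfg.n_months)
    else:
        le, h_obs = le_clean, h
    et = metphys.et_from_le(le_clean) * SECONDS_PER_MONTH   # kg m-2 per month
    gpp = cfg.uwue_true * et / np.sqrt(metphys.hpa_to_kpa(vpd))
    if cfg.flux_noise_sd > 0:
        gpp = gpp * rng.lognormal(0.0, cfg.flux_noise_sd, cfg.n_months)

    idx = pd.date_range("2000-01-01", periods=cfg.n_months, freq="MS")
    data = pd.DataFrame({
        "gpp": gpp, "le": le, "h": h_obs, "vpd": vpd, "ta": ta, "rh": rh,
        "ws": ws, "ustar": ustar, "pressure": cfg.pressure_kpa,
        "et": metphys.et_from_le(le) * SECONDS_PER_MONTH,
    }, index=idx)
    truth = {"true_gc": float(np.mean(gc)), "uwue_true": cfg.uwue_true,
             "flux_noise_sd": cfg.flux_noise_sd, "seed": cfg.seed}
    return data, truth


def gen_warming_sites(n_sites: int = 67, dta_mean: float = 2.7, dta_sd: float = 0.6,
                      ta_c_range: Tuple[float, float] = (5.0, 15.0),
                      vpd_a: float = 2.0, vpd_b: float = 0.06,
                      vpd_lognoise_sd: float = 0.05, effect_slope: float = 0.0,
                      growth_noise_sd: float = 0.55, growth_base: float = 100.0,
                      seed: int = 0) -> Tuple[pd.DataFrame, Dict]:
    """Synthesis table of paired warming experiments with a planted VPD effect.

    Per site: control Ta drawn uniformly, the warming increment normally
    (defaults 2.7 +/- 0.6 degC, the synthesis-scale warming), VPD following
    the exponential coupling with small lognormal site noise, RH derived by
    inverting the saturation curve, and the log growth response equal to
    ``effect_slope * dVPD`` plus noise.  ``effect_slope = 0`` is the neutral
    scenario; the default noise level sizes the 67-site regression standard
    error near 0.27.
    """
    if n_sites < 3:
        raise InvalidInputError("need at least 3 sites")
    rng = np.random.default_rng(seed)
    ta_c = rng.uniform(*ta_c_range, n_sites)
    ta_w = ta_c + rng.normal(dta_mean, dta_sd, n_sites)
    noise_c = rng.normal(0.0, vpd_lognoise_sd, n_sites)
    noise_w = rng.normal(0.0, vpd_lognoise_sd, n_sites)
    vpd_c = vpd_a * np.exp(vpd_b * ta_c) * np.exp(noise_c)
    vpd_w = vpd_a * np.exp(vpd_b * ta_w) * np.exp(noise_w)
    rh_c = metphys.rh_from_vpd(ta_c, vpd_c)
    rh_w = metphys.rh_from_vpd(ta_w, vpd_w)
    dvpd_true = vpd_a * (np.exp(vpd_b * ta_w) - np.exp(vpd_b * ta_c))
    growth_c = growth_base * np.exp(rng.normal(0.0, 0.1, n_sites))
    log_ratio = effect_slope * dvpd_true + rng.normal(0.0, growth_noise_sd, n_sites)
    growth_w = growth_c * np.exp(log_ratio)
    table = pd.DataFrame({
        "site_id": [f"S{i:03d}" for i in range(n_sites)],
        "ta_c": ta_c, "ta_w": ta_w, "rh_c": rh_c, "rh_w": rh_w,
        "vpd_c": vpd_c, "vpd_w": vpd_w,
        "growth_c": growth_c, "growth_w": growth_w, "metric": "NPP",
    })
    truth = {"effect_slope": effect_slope, "vpd_a": vpd_a, "vpd_b": vpd_b,
             "dta_mean": dta_mean, "dta_sd": dta_sd,
             "growth_noise_sd": growth_noise_sd, "seed": seed}
    return table, truth


_RAW_SCALES = {        # realistic raw units for the six-trait table
    "vwc": (15.0, 3.0), "cwd": (30.0, 10.0), "soc": (0.7, 0.3),
    "bd": (1.2, 0.15), "uwue": (1.5, 0.3), "pcor_et_vpd": (0.05, 0.15),
}


def gen_rf_table(n_rows: int = 2000, betas: Optional[Dict[str, float]] = None,
                 noise_sd: float = 0.5, predictor_corr: float = 0.1,
                 seed: int = 0) -> Tuple[pd.DataFrame, Dict]:
    """Six-predictor pixel table with a planted additive response.

    The response (named ``pcor_gpp_vpd``) is ``sum_j beta_j * z_j + eps`` on
    the z scale, affinely mapped to a partial-correlation-like range.  The
    truth sidecar carries the planted betas and the implied perturbation
    sensitivity ``beta_j / sd(response_z)`` — what the +1-SD perturbation of
    predictor j changes in the response, in raw-response SD units.
    """
    cols = list(_RAW_SCALES)
    betas = dict(betas) if betas is not None else {
        "vwc": 0.5, "cwd": -0.7, "soc": 0.45, "bd": -0.4,
        "uwue": -0.8, "pcor_et_vpd": 1.1}
    rng = np.random.default_rng(seed)
    k = len(cols)
    C = np.full((k, k), predictor_corr) + (1 - predictor_corr) * np.eye(k)
    Zs = rng.standard_normal((n_rows, k)) @ np.linalg.cholesky(C).T
    beta_vec = np.array([betas.get(c, 0.0) for c in cols])
    y_z = Zs @ beta_vec + rng.normal(0.0, noise_sd, n_rows)
    sd_yz = float(np.sqrt(beta_vec @ C @ beta_vec + noise_sd ** 2))
    y = 0.05 + 0.15 * y_z / sd_yz           # pcor-like scale; sensitivity invariant
    df = pd.DataFrame({c: _RAW_SCALES[c][0] + _RAW_SCALES[c][1] * Zs[:, i]
                       for i, c in enumerate(cols)})
    df["pcor_gpp_vpd"] = y
    truth = {"betas": betas, "noise_sd": noise_sd,
             "expected_sensitivity": {c: float(b / sd_yz)
                                      for c, b in zip(cols, beta_vec)},
             "seed": seed}
    return df, truth


def gen_mediation_data(n_rows: int = 2000, a1: float = 0.5, a2: float = 0.0,
                       d21: float = 0.4, b1: float = 0.0, b2: float = 0.6,
                       c_prime: float = 0.0,
                       seed: int = 0) -> Tuple[pd.DataFrame, Dict]:
    """Serial-mediation sample x -> m1 -> m2 -> y with planted *standardized* paths.

    x is standard normal and each downstream residual variance is chosen so
    every variable has unit population variance, making the structural
    coefficients equal to the standardized paths the analysis estimates.
    The truth sidecar carries the paths and ``ind_serial = a1*d21*b2``.
    Raises if the requested paths imply a negative residual variance.
    """
    rng = np.random.default_rng(seed)
    # population covariances implied by unit-variance upstream variables
    cov_x_m1 = a1
    var_m2_sys = a2 ** 2 + d21 ** 2 + 2 * a2 * d21 * cov_x_m1
    cov_x_m2 = a2 + d21 * a1
    cov_m1_m2 = a2 * a1 + d21
    var_y_sys = (c_prime ** 2 + b1 ** 2 + b2 ** 2
                 + 2 * (c_prime * b1 * cov_x_m1 + c_prime * b2 * cov_x_m2
                        + b1 * b2 * cov_m1_m2))
    s1, s2, s3 = 1 - a1 ** 2, 1 - var_m2_sys, 1 - var_y_sys
    if min(s1, s2, s3) <= 0:
        raise InvalidInputError("path coefficients imply non-positive residual variance")
    x = rng.standard_normal(n_rows)
    m1 = a1 * x + np.sqrt(s1) * rng.standard_normal(n_rows)
    m2 = a2 * x + d21 * m1 + np.sqrt(s2) * rng.standard_normal(n_rows)
    y = (c_prime * x + b1 * m1 + b2 * m2
         + np.sqrt(s3) * rng.standard_normal(n_rows))
    df = pd.DataFrame({"x": x, "m1": m1, "m2": m2, "y": y})
    truth = {"a1": a1, "a2": a2, "d21": d21, "b1": b1, "b2": b2,
             "c_prime": c_prime, "ind_serial": a1 * d21 * b2, "seed": seed}
    return df, truth


def gen_trait_table(n_rows: int = 3000, noise_sd: float = 0.4,
                    seed: int = 0) -> Tuple[pd.DataFrame, Dict]:
    """Pixel table coupling soil/water traits, water-use strategy and VPD effect.

    Structure (z scale): wetter and more organic soils lower uWUE and raise
    the transpiration–VPD coupling; the VPD effect on GPP falls with uWUE
    and rises with the transpiration–VPD coupling.  The implied indirect
    effects are positive for VWC and SOC, negative for CWD and BD — the
    qualitative pattern the mediation battery should recover.
    """
    rng = np.random.default_rng(seed)
    z = {c: rng.standard_normal(n_rows) for c in ("vwc", "cwd", "soc", "bd")}
    e = lambda: rng.normal(0.0, noise_sd, n_rows)
    uwue_z = -0.4 * z["vwc"] + 0.3 * z["cwd"] - 0.35 * z["soc"] + 0.3 * z["bd"] + e()
    et_z = 0.35 * z["vwc"] - 0.3 * z["cwd"] + 0.3 * z["soc"] - 0.25 * z["bd"] \
        - 0.3 * uwue_z + e()
    y_z = -0.5 * uwue_z + 0.6 * et_z + e()
    df = pd.DataFrame({c: _RAW_SCALES[c][0] + _RAW_SCALES[c][1] * z[c]
                       for c in ("vwc", "cwd", "soc", "bd")})
    df["uwue"] = _RAW_SCALES["uwue"][0] + _RAW_SCALES["uwue"][1] * uwue_z
    df["pcor_et_vpd"] = _RAW_SCALES["pcor_et_vpd"][0] + _RAW_SCALES["pcor_et_vpd"][1] * et_z
    df["pcor_gpp_vpd"] = 0.05 + 0.15 * y_z / y_z.std()
    truth = {"indirect_sign": {"vwc": 1, "soc": 1, "cwd": -1, "bd": -1},
             "noise_sd": noise_sd, "seed": seed}
    return df, truth
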