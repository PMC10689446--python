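"""Readers, writers, the flux-site quality filter, and the pipeline runner.

Flux CSVs follow the FLUXNET-2015 dialect (monthly TIMESTAMP as YYYYMM,
nighttime-partitioned GPP in ``GPP_NT_VUT_REF``); a ``column_map`` resolves
header synonyms.  Units are normalized on ingest: VPD to hPa, LE/H to W m-2,
pressure to kPa.  Mandatory variables without a resolvable column raise a
schema error listing them — readers never silently coerce.

NetCDF is written through xarray's scipy backend (NetCDF3 classic), which
round-trips bit-exactly for masks and to float precision for data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .exceptions import InvalidInputError, SchemaError

logger = logging.getLogger(__name__)

__all__ = ["SiteRecord", "load_flux_csv", "quality_filter",
           "write_netcdf", "read_netcdf", "run_pipeline"]

#: FLUXNET-2015-style header -> internal name
DEFAULT_COLUMN_MAP = {
    "GPP_NT_VUT_REF": "gpp", "LE_F_MDS": "le", "H_F_MDS": "h",
    "TA_F": "ta", "VPD_F": "vpd", "P_F": "precip", "SW_IN_F": "sw_in",
    "WS_F": "ws", "USTAR": "ustar", "PA_F": "pressure",
    "NEE_VUT_REF_QC": "qc",
}
MANDATORY = ("gpp", "le", "h", "ta", "vpd")
CROPLAND_IGBP = ("CRO",)


@dataclass
class SiteRecord:
    """One flux tower: monthly series plus site metadata."""
    site_id: str
    lat: float
    lon: float
    data: pd.DataFrame                    # monthly DatetimeIndex
    qc: Optional[pd.Series] = None        # good-quality fraction per month
    igbp: Optional[str] = None

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise InvalidInputError(f"latitude {self.lat} outside [-90, 90]")
        if len(self.data) and not self.data.index.is_monotonic_increasing:
            raise InvalidInputError("months must be chronological")

    @property
    def start_year(self) -> int:
        return int(self.data.index[0].year)

    @property
    def end_year(self) -> int:
        return int(self.data.index[-1].year)


def load_flux_csv(path, column_map: Optional[Dict[str, str]] = None,
                  site_id: Optional[str] = None, lat: float = 0.0,
                  lon: float = 0.0, igbp: Optional[str] = None) -> SiteRecord:
    """Parse a FLUXNET-style monthly CSV into a :class:`SiteRecord`.

    ``column_map`` maps source headers to internal names and is merged over
    the FLUXNET defaults.  Missing mandatory variables raise
    :class:`~peatvpd.exceptions.SchemaError` naming them.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    ts_col = next((c for c in ("TIMESTAMP", "TIMESTAMP_START", "timestamp")
                   if c in raw.columns), None)
    if ts_col is None:
        raise SchemaError("no TIMESTAMP column")
    idx = pd.to_datetime(raw[ts_col].astype(str).str.slice(0, 6), format="%Y%m")
    data = {}
    for src, dst in cmap.items():
        if src in raw.columns:
            data[dst] = pd.to_numeric(raw[src], errors="coerce").to_numpy()
    missing = [m for m in MANDATORY if m not in data]
    if missing:
        raise SchemaError(f"missing mandatory columns (after mapping): {missing}")
    df = pd.DataFrame(data, index=idx).sort_index()
    df[df <= -9990] = np.nan        # FLUXNET missing sentinel
    qc = df.pop("qc") if "qc" in df.columns else None
    return SiteRecord(site_id=site_id or path.stem, lat=lat, lon=lon,
                      data=df, qc=qc, igbp=igbp)


def quality_filter(rec: SiteRecord, qc_threshold: float = 0.75,
                   min_good_months: int = 15, min_span_years: int = 3,
                   exclude_cropland: bool = True) -> Optional[SiteRecord]:
    """Apply the tower quality filter; returns None for rejected sites.

    Months with a good-quality fraction below ``qc_threshold`` (strictly; a
    month at exactly 0.75 is kept) are dropped.  A site is retained only if
    it keeps strictly more than ``min_good_months`` months AND those months
    span at least ``min_span_years`` calendar years — both conditions, since
    either alone under-determines the record length.  Cropland towers
    (IGBP class CRO) are excluded to avoid managed-vegetation signals.
    """
    if exclude_cropland and rec.igbp in CROPLAND_IGBP:
        logger.info("site %s rejected: cropland (IGBP %s)", rec.site_id, rec.igbp)
        return None
    if rec.qc is None:
        raise InvalidInputError("quality_filter requires per-month qc fractions")
    good = rec.qc >= qc_threshold
    kept = rec.data.loc[good.to_numpy()]
    n_good = int(good.sum())
    span = (kept.index[-1].year - kept.index[0].year + 1) if n_good else 0
    if n_good <= min_good_months or span < min_span_years:
        logger.info("site %s rejected: %d good months over %d years",
                    rec.site_id, n_good, span)
        return None
    return SiteRecord(site_id=rec.site_id, lat=rec.lat, lon=rec.lon,
                      data=kept, qc=rec.qc.loc[good.to_numpy()], igbp=rec.igbp)


def write_netcdf(ds: xr.Dataset, path):
    """Write a dataset as NetCDF3 classic (scipy backend)."""
    enc = {v: {"dtype": "float64"} for v in ds.data_vars
           if np.issubdtype(ds[v].dtype, np.floating)}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_netcdf(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "grid": {"n_lat": 15, "n_lon": 15, "target_pcor": 0.2},
    "trait_table": {"n_rows": 1500},
    "warming": {"n_sites": 67, "effect_slope": 0.0},
    "pcor": {"alpha": 0.05, "min_valid_frac": 0.8},
    "sensitivity": {"n_trees": 200},
    "mediation": {"n_boot": 1000},
}


def run_pipeline(config=None, outdir="pipeline_out") -> Path:
    """Run simulate -> flux metrics -> PCOR map -> summaries -> sensitivity
    -> mediation on synthetic inputs, writing artifacts and a manifest.

    ``config`` is a dict, a YAML path, or None for defaults.  Outputs are a
    NetCDF r/p map, CSV regional summaries, JSON sensitivity and mediation
    results, the truth sidecars, and ``manifest.json`` (config hash, seed,
    input checksums).  Reruns with the same config are bit-identical.
    """
    from . import gridstats, mediation, rfsens, synth, warming, metphys

    if config is None:
        cfg = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = {**DEFAULT_PIPELINE_CONFIG, **yaml.safe_load(fh)}
    else:
        cfg = {**DEFAULT_PIPELINE_CONFIG, **config}
    seed = int(cfg["seed"])
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        grid = synth.gen_gridded(synth.GridGenConfig(seed=seed, **cfg["grid"]))
        grid.write(out / "grid")
        traits, trait_truth = synth.gen_trait_table(seed=seed + 1, **cfg["trait_table"])
        traits.to_csv(out / "traits.csv", index=False)
        flux, flux_truth = synth.gen_flux_tower(synth.FluxGenConfig(seed=seed + 2))
        flux.to_csv(out / "flux.csv")

        stage("flux-metrics")
        gc = metphys.canopy_conductance(flux["le"].to_numpy(), flux["h"].to_numpy(),
                                        flux["vpd"].to_numpy(), flux["ws"].to_numpy(),
                                        flux["ustar"].to_numpy(), flux["ta"].to_numpy())
        uw = metphys.uwue(flux["gpp"].to_numpy(),
                          metphys.hpa_to_kpa(flux["vpd"].to_numpy()),
                          flux["et"].to_numpy())
        results["flux_metrics"] = {"median_gc_mm_s": float(np.nanmedian(gc)),
                                   "true_gc_mm_s": flux_truth["true_gc"],
                                   "median_uwue": float(np.nanmedian(uw)),
                                   "uwue_true": flux_truth["uwue_true"]}

        stage("pcor-map")
        d = grid.data
        fit = gridstats.PcorMap(d["gpp"], d["vpd"],
                                [d["ta"], d["radiation"], d["wind"], d["precip"]],
                                dim="year",
                                min_valid_frac=cfg["pcor"]["min_valid_frac"]).fit()
        fit.to_netcdf(out / "pcor_map.nc")

        stage("summaries")
        alpha = cfg["pcor"]["alpha"]
        summaries = [fit.region_summary(alpha=alpha, label="all")]
        summaries += fit.extent_gradient(np.asarray(d["extent"]), alpha=alpha)
        summaries += list(fit.aridity_summaries(np.asarray(d["ai"]), alpha=alpha).values())
        fit.summaries_to_csv(summaries, out / "region_summaries.csv")
        s_all = summaries[0]
        results["pcor"] = {"mean_r": s_all.mean_r, "pct_sig_neg": s_all.pct_sig_neg,
                           "pct_sig_pos": s_all.pct_sig_pos, "n_pixels": s_all.n_pixels}

        stage("warming")
        sites, site_truth = synth.gen_warming_sites(seed=seed + 3, **cfg["warming"])
        sites.to_csv(out / "warming_sites.csv", index=False)
        wres = warming.analyze_warming_synthesis(sites)
        results["warming"] = {"slope": wres["regression"].slope,
                              "se": wres["regression"].se,
                              "p": wres["regression"].p,
                              "neutral": bool(wres["regression"].neutral),
                              "fit_a": wres["fit"].a, "fit_b": wres["fit"].b}

        stage("sensitivity")
        forest = rfsens.SensitivityForest(traits, response="pcor_gpp_vpd",
                                          n_trees=cfg["sensitivity"]["n_trees"]).fit(seed=seed + 4)
        sens = forest.sensitivities(force=True)
        results["sensitivity"] = {"model_r": forest.model_r,
                                  **{k: float(v) for k, v in sens.items()}}
        with open(out / "sensitivities.json", "w") as fh:
            json.dump(results["sensitivity"], fh, indent=1)

        stage("mediation")
        med = mediation.mediation_battery(traits, n_boot=cfg["mediation"]["n_boot"],
                                          seed=seed + 5)
        med_out = {x: {"ind_serial": r.ind_serial, "ind_m1": r.ind_m1,
                       "ind_m2": r.ind_m2, "c_prime": r.c_prime,
                       "significant_serial": bool(r.significant["ind_serial"])}
                   for x, r in med.items()}
        results["mediation"] = med_out
        with open(out / "mediation.json", "w") as fh:
            json.dump(med_out, fh, indent=1)
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed: {e}") from e

    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=1)
    cfg_blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "config_sha256": hashlib.sha256(cfg_blob).hexdigest(),
        "seed": seed,
        "inputs": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))},
        "package": "peatvpd",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
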