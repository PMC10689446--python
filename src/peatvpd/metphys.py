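"""Meteorological and ecophysiological primitives.

Closed-form building blocks used throughout the package:

* saturation vapor pressure (Magnus form) and vapor pressure deficit (VPD),
  either from relative humidity or from actual vapor pressure;
* bulk canopy conductance ``Gc`` obtained by inverting the Penman–Monteith
  equation from eddy-covariance fluxes (and the matching forward model);
* underlying water-use efficiency uWUE = GPP * sqrt(VPD) / ET, the proxy for
  plant water-use strategy;
* the growing-season mask (months with mean air temperature above 0 degC).

Unit conventions: air temperature in degC, vapor pressures in hPa everywhere
internally, atmospheric pressure in kPa, fluxes in W m-2, conductance in
mm s-1.  uWUE is the one kPa-facing quantity; its VPD argument is explicitly
in kPa and callers must convert (``hpa_to_kpa``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InvalidInputError

logger = logging.getLogger(__name__)

#: von Karman constant (dimensionless); fixed.
VON_KARMAN = 0.4

#: Default latent heat of vaporization used for LE -> ET and for the
#: psychrometric constant, J kg-1.  2.44e6 J kg-1 (= 2.44 MJ kg-1) is the
#: textbook value near 20 degC.
LATENT_HEAT_J_PER_KG = 2.44e6

#: Specific heat of moist air at constant pressure, J kg-1 K-1.
CP_AIR = 1013.0

#: Specific gas constant of dry air, J kg-1 K-1.
R_DRY_AIR = 287.05


def _asfloat(x):
    a = np.asarray(x, dtype=float)
    return a


def hpa_to_kpa(p_hpa):
    """Convert a pressure-like quantity from hPa to kPa."""
    return _asfloat(p_hpa) / 10.0


def svp(ta):
    """Saturation vapor pressure (hPa) at air temperature ``ta`` (degC).

    Magnus-type form ``6.11 * exp(17.27*Ta / (Ta + 273.3))``; strictly
    increasing in ``ta``.
    """
    ta = _asfloat(ta)
    if not np.all(np.isfinite(ta)):
        raise InvalidInputError("svp: air temperature must be finite")
    return 6.11 * np.exp(17.27 * ta / (ta + 273.3))


def vpd_from_rh(ta, rh):
    """VPD (hPa) from air temperature (degC) and relative humidity (%).

    ``svp(ta) * (1 - rh/100)``; non-negative for rh in [0, 100].
    """
    ta = _asfloat(ta)
    rh = _asfloat(rh)
    if not np.all(np.isfinite(rh)) or np.any(rh < 0) or np.any(rh > 100):
        raise InvalidInputError("vpd_from_rh: rh must lie in [0, 100]")
    return svp(ta) * (1.0 - rh / 100.0)


def vpd_from_avp(ta, avp):
    """VPD (hPa) as saturation minus actual vapor pressure.

    Negative values (supersaturation, AVP > SVP, occasionally present in
    gridded products) are retained and logged, not zeroed.
    """
    avp = _asfloat(avp)
    if np.any(avp < 0):
        raise InvalidInputError("vpd_from_avp: avp must be non-negative")
    out = svp(ta) - avp
    n_neg = int(np.sum(out < 0))
    if n_neg:
        logger.warning("vpd_from_avp: %d supersaturated values (VPD < 0) retained", n_neg)
    return out


def rh_from_vpd(ta, vpd):
    """Relative humidity (%) implied by temperature and VPD (hPa)."""
    return 100.0 * (1.0 - _asfloat(vpd) / svp(ta))


@dataclass(frozen=True)
class PhysConstants:
    """Thermodynamic quantities entering the Penman–Monteith inversion.

    Attributes
    ----------
    delta : slope of the saturation-vapor-pressure curve vs Ta, Pa K-1.
    gamma : psychrometric constant, Pa K-1.
    rho : moist-air density, kg m-3.
    cp : specific heat of air, J kg-1 K-1.
    k : von Karman constant (0.4, fixed).
    latent_heat : latent heat of vaporization, J kg-1.
    """

    delta: np.ndarray
    gamma: np.ndarray
    rho: np.ndarray
    cp: float = CP_AIR
    k: float = VON_KARMAN
    latent_heat: float = LATENT_HEAT_J_PER_KG

    @classmethod
    def from_met(cls, ta, pressure_kpa=101.325, cp=CP_AIR,
                 latent_heat=LATENT_HEAT_J_PER_KG):
        """Derive (delta, gamma, rho) from air temperature and pressure.

        delta is the analytic derivative of the Magnus saturation curve
        (converted to Pa K-1); gamma = cp*P / (0.622*latent_heat); rho from
        the ideal-gas law for (dry) air at Ta.
        """
        ta = _asfloat(ta)
        p_pa = _asfloat(pressure_kpa) * 1000.0
        # d(SVP)/dTa of the Magnus form, hPa/K -> Pa/K
        delta = 100.0 * svp(ta) * (17.27 * 273.3) / (ta + 273.3) ** 2
        gamma = cp * p_pa / (0.622 * latent_heat)
        rho = p_pa / (R_DRY_AIR * (ta + 273.15))
        return cls(delta=delta, gamma=np.broadcast_to(gamma, delta.shape).copy()
                   if delta.shape else np.asarray(gamma, float),
                   rho=rho, cp=cp, k=VON_KARMAN, latent_heat=latent_heat)


def aerodynamic_resistance(ws, ustar, k=VON_KARMAN):
    """Aerodynamic resistance (s m-1) from wind speed and friction velocity.

    ``ra = ws*k^2 / ln(exp(k*ws/u*) - 0.7)^2`` with the natural logarithm.
    The formula yields values far below textbook aerodynamic resistances for
    typical inputs; it is applied verbatim as the package's convention and the
    discrepancy is documented rather than corrected.

    Degenerate inputs (argument of the log at or below 0, or a vanishing
    squared log term) raise for scalars and are masked to NaN for arrays.
    """
    ws = _asfloat(ws)
    ustar = _asfloat(ustar)
    if np.any(ws <= 0) or np.any(ustar <= 0):
        raise InvalidInputError("aerodynamic_resistance: ws and u* must be positive")
    arg = np.exp(k * ws / ustar) - 0.7
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(arg > 0, np.log(np.where(arg > 0, arg, 1.0)), np.nan)
        denom = logterm ** 2
        bad = ~np.isfinite(denom) | (denom < 1e-10)
        ra = np.where(bad, np.nan, ws * k ** 2 / np.where(bad, 1.0, denom))
    if ra.ndim == 0:
        if bad:
            raise DegenerateInputError(
                "aerodynamic_resistance: log term vanishes (exp(k*ws/u*) too close to 1.7)")
        return float(ra)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("aerodynamic_resistance: %d degenerate values masked", n_bad)
    return ra


def canopy_conductance(le, h, vpd_hpa, ws, ustar, ta, pressure_kpa=101.325,
                       constants=None):
    """Bulk canopy conductance Gc (mm s-1) by Penman–Monteith inversion.

    ``Gc = [ (delta/gamma * H/LE - 1)*ra + (rho*cp/gamma) * VPD/LE ]^-1``
    with ra from :func:`aerodynamic_resistance` and VPD converted to Pa.

    Non-physical results (bracketed term <= 0, i.e. a negative or infinite
    conductance) are masked to NaN rather than clipped, and counted in the
    package log: inversion of noisy fluxes routinely produces them, and
    silent clipping would bias regional means.
    """
    le = _asfloat(le)
    h = _asfloat(h)
    vpd_pa = _asfloat(vpd_hpa) * 100.0
    if np.any(le == 0):
        raise InvalidInputError("canopy_conductance: LE must be nonzero")
    if np.any(vpd_pa <= 0):
        raise InvalidInputError("canopy_conductance: VPD must be positive")
    c = constants or PhysConstants.from_met(ta, pressure_kpa)
    ra = aerodynamic_resistance(ws, ustar)
    bracket = (c.delta / c.gamma * h / le - 1.0) * ra + (c.rho * c.cp / c.gamma) * vpd_pa / le
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(bracket > 0, 1000.0 / np.where(bracket > 0, bracket, 1.0), np.nan)
    n_rej = int(np.sum(~(np.asarray(bracket) > 0)))
    if n_rej:
        logger.warning("canopy_conductance: %d non-physical inversions masked", n_rej)
    if gc.ndim == 0:
        return float(gc)
    return gc


def penman_monteith_le(gc_mm_s, h, vpd_hpa, ws, ustar, ta,
                       pressure_kpa=101.325, constants=None):
    """Forward Penman–Monteith latent heat flux (W m-2) at known Gc.

    Exact algebraic inverse of :func:`canopy_conductance`:
    ``LE = (delta*H*ra + rho*cp*VPD) / (gamma*(1/Gc + ra))`` with Gc in m s-1.
    Used by the synthetic flux-tower generator and as the round-trip oracle.
    """
    gc_ms = _asfloat(gc_mm_s) / 1000.0
    vpd_pa = _asfloat(vpd_hpa) * 100.0
    c = constants or PhysConstants.from_met(ta, pressure_kpa)
    ra = aerodynamic_resistance(ws, ustar)
    le = (c.delta * _asfloat(h) * ra + c.rho * c.cp * vpd_pa) / (c.gamma * (1.0 / gc_ms + ra))
    if le.ndim == 0:
        return float(le)
    return le


def et_from_le(le, coefficient=LATENT_HEAT_J_PER_KG):
    """Evaporative water flux (kg H2O m-2 s-1) from latent heat (W m-2).

    Divides by the latent-heat coefficient.  The default interprets the
    conventional "2.44" conversion factor as 2.44 MJ kg-1 (2.44e6 J kg-1);
    pass ``coefficient=2.44`` for the literal J kg-1 reading.
    """
    le = _asfloat(le)
    if not np.all(np.isfinite(le)):
        raise InvalidInputError("et_from_le: LE must be finite")
    out = le / coefficient
    if out.ndim == 0:
        return float(out)
    return out


def uwue(gpp, vpd_kpa, et):
    """Underlying water-use efficiency, g C kPa^0.5 kg-1 H2O.

    ``uWUE = GPP * sqrt(VPD) / ET`` with GPP in g C m-2, VPD in **kPa**, and
    ET in kg H2O m-2 over the same period.  High uWUE marks a conservative
    ("reduce expenditure") water-use strategy, low uWUE an "open" strategy.
    Non-positive ET leaves uWUE undefined (NaN).
    """
    gpp = _asfloat(gpp)
    vpd_kpa = _asfloat(vpd_kpa)
    et = _asfloat(et)
    if np.any(vpd_kpa < 0):
        raise InvalidInputError("uwue: VPD must be non-negative (and in kPa)")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(et > 0, gpp * np.sqrt(vpd_kpa) / np.where(et > 0, et, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def growing_season_mask(ta, climatology=False):
    """Boolean mask of growing-season months: mean Ta strictly above 0 degC.

    Parameters
    ----------
    ta : pandas.Series with a monthly DatetimeIndex/PeriodIndex, or array.
        Monthly mean air temperature, degC.  A DatetimeIndex is validated to
        be monthly; plain arrays are trusted to be monthly.
    climatology : bool
        If True, the mask is computed per *calendar month* from the
        multi-year mean Ta and broadcast back to every month of the record
        (the convention for defining a fixed seasonal window).

    Returns
    -------
    Boolean pandas.Series (or ndarray for array input), True where the
    (climatological) monthly mean exceeds 0 degC; the inequality is strict.
    """
    import pandas as pd

    if isinstance(ta, pd.Series):
        idx = ta.index
        if isinstance(idx, pd.DatetimeIndex):
            if len(idx) >= 3:
                months = idx.to_period("M").asi8
                if not np.all(np.diff(months) == 1):
                    raise InvalidInputError("growing_season_mask: index is not consecutive monthly")
        elif isinstance(idx, pd.PeriodIndex):
            if idx.freqstr not in ("M", "ME"):
                raise InvalidInputError("growing_season_mask: PeriodIndex must be monthly")
        if climatology:
            if isinstance(idx, pd.PeriodIndex):
                cal_month = idx.month
            else:
                cal_month = idx.month
            clim = ta.groupby(cal_month).mean()
            return pd.Series(clim.reindex(cal_month).to_numpy() > 0.0, index=idx)
        return ta > 0.0
    arr = _asfloat(ta)
    if arr.ndim != 1:
        raise InvalidInputError("growing_season_mask: expected a 1-d monthly series")
    if climatology:
        if arr.size % 12 != 0:
            raise InvalidInputError("growing_season_mask: climatology mode needs whole years")
        clim = arr.reshape(-1, 12).mean(axis=0)
        return np.tile(clim > 0.0, arr.size // 12)
    return arr > 0.0
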