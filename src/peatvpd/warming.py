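"""Warming-experiment analysis.

Paired control/warming treatment tests (paired t with a Shapiro–Wilk
normality check and a Wilcoxon signed-rank fallback), the exponential
coupling of VPD to air temperature, simulated warming-induced VPD increases
at synthesis sites, and the cross-site regression of the vegetation growth
response on the VPD increase.  A slope whose confidence interval covers zero
is the "neutral VPD effect" outcome.

The growth response is the log response ratio ln(growth_warming /
growth_control) by default; raw-ratio and difference encodings are
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import metphys
from .exceptions import (AlignmentError, InvalidInputError, SingularDesignError)

logger = logging.getLogger(__name__)

__all__ = [
    "WarmingPair", "PairedTestResult", "ExpFit", "RegressionResult",
    "paired_warming_test", "fit_ta_vpd_exponential", "simulate_vpd_delta",
    "vpd_effect_regression", "growth_response", "analyze_warming_synthesis",
]


@dataclass
class WarmingPair:
    """Time-aligned control and warming series for one experimental site."""
    site_id: str
    control: pd.DataFrame     # columns among ta, rh, vpd, growth
    warming: pd.DataFrame
    growth_metric: str = "NPP"

    def __post_init__(self):
        if len(self.control) != len(self.warming):
            raise AlignmentError("control and warming series must be time-aligned")


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t test of warming minus control, with normality diagnostics."""
    t: float
    df: int
    p: float
    shapiro_p: float
    mean_diff: float
    se_diff: float
    wilcoxon_p: Optional[float] = None
    degenerate: bool = False


@dataclass(frozen=True)
class ExpFit:
    """Exponential Ta–VPD coupling VPD = a * exp(b * Ta).

    ``r`` is the Pearson correlation between fitted and observed VPD on the
    original (not log) scale; ``n_filtered`` counts non-positive VPD values
    excluded from the log-linear fit.
    """
    a: float
    b: float
    r: float
    n: int
    n_filtered: int = 0


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    se: float
    p: float
    n: int
    intercept: float
    ci_low: float
    ci_high: float

    @property
    def neutral(self) -> bool:
        """True when the slope CI covers zero (no detectable VPD effect)."""
        return self.ci_low <= 0.0 <= self.ci_high


def paired_warming_test(pair, variable: str = None,
                        shapiro_alpha: float = 0.05) -> PairedTestResult:
    """Paired t test of a variable between warming and control treatments.

    Accepts a :class:`WarmingPair` plus a variable name, or two equal-length
    arrays (control, warming) as a tuple.  Differences are warming - control.
    A Shapiro–Wilk test is run on the differences; when its p-value is at or
    below ``shapiro_alpha`` a Wilcoxon signed-rank p is attached as the
    nonparametric fallback.

    Zero-variance differences are degenerate: reported with t=0, p=1 when the
    common difference is 0 (identical treatments) and NaN statistics for a
    nonzero constant shift (the t statistic is undefined).
    """
    if isinstance(pair, WarmingPair):
        c = np.asarray(pair.control[variable], dtype=float)
        w = np.asarray(pair.warming[variable], dtype=float)
    else:
        c, w = (np.asarray(v, dtype=float) for v in pair)
    if c.size != w.size:
        raise AlignmentError("control and warming differ in length")
    ok = np.isfinite(c) & np.isfinite(w)
    c, w = c[ok], w[ok]
    n = c.size
    if n < 3:
        raise InvalidInputError("need at least 3 paired observations")
    d = w - c
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    if sd <= 1e-10 * max(1.0, abs(mean_diff)):
        if mean_diff == 0.0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, shapiro_p=np.nan,
                                    mean_diff=0.0, se_diff=0.0, degenerate=True)
        return PairedTestResult(t=np.nan, df=n - 1, p=np.nan, shapiro_p=np.nan,
                                mean_diff=mean_diff, se_diff=0.0, degenerate=True)
    t_stat, p = stats.ttest_rel(w, c)
    sh_p = float(stats.shapiro(d)[1])
    wilcoxon_p = None
    if sh_p <= shapiro_alpha:
        try:
            wilcoxon_p = float(stats.wilcoxon(d).pvalue)
        except ValueError:
            wilcoxon_p = np.nan
    return PairedTestResult(t=float(t_stat), df=n - 1, p=float(p), shapiro_p=sh_p,
                            mean_diff=mean_diff, se_diff=float(se),
                            wilcoxon_p=wilcoxon_p)


def fit_ta_vpd_exponential(ta, vpd) -> ExpFit:
    """Fit VPD = a * exp(b * Ta) by least squares on ln(VPD).

    The log-linear fit is closed-form and deterministic.  Non-positive VPD
    values cannot enter the log and are filtered with a logged count.  The
    reported ``r`` correlates fitted against observed VPD on the original
    scale.
    """
    ta = np.asarray(ta, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    if ta.size != vpd.size:
        raise AlignmentError("ta and vpd differ in length")
    ok = np.isfinite(ta) & np.isfinite(vpd)
    pos = ok & (vpd > 0)
    n_filtered = int(ok.sum() - pos.sum())
    if n_filtered:
        logger.warning("fit_ta_vpd_exponential: filtered %d non-positive VPD values", n_filtered)
    ta, vpd = ta[pos], vpd[pos]
    if ta.size < 5:
        raise InvalidInputError("need at least 5 positive-VPD observations")
    if np.ptp(ta) == 0:
        raise SingularDesignError("ta is constant")
    b, ln_a = np.polyfit(ta, np.log(vpd), 1)
    a = float(np.exp(ln_a))
    fitted = a * np.exp(b * ta)
    if np.std(fitted) > 0 and np.std(vpd) > 0:
        r = float(stats.pearsonr(fitted, vpd)[0])
    else:
        r = np.nan
    return ExpFit(a=a, b=float(b), r=r, n=int(ta.size), n_filtered=n_filtered)


def simulate_vpd_delta(fit: ExpFit, ta_control, ta_warm):
    """Warming-induced VPD increase a*exp(b*ta_warm) - a*exp(b*ta_control), hPa."""
    ta_c = np.asarray(ta_control, dtype=float)
    ta_w = np.asarray(ta_warm, dtype=float)
    out = fit.a * (np.exp(fit.b * ta_w) - np.exp(fit.b * ta_c))
    if out.ndim == 0:
        return float(out)
    return out


def growth_response(growth_control, growth_warming, mode: str = "log_ratio"):
    """Per-site vegetation growth response to warming.

    ``log_ratio`` (default): ln(warming/control); ``ratio``: warming/control;
    ``difference``: warming - control.
    """
    c = np.asarray(growth_control, dtype=float)
    w = np.asarray(growth_warming, dtype=float)
    if mode == "log_ratio":
        if np.any(c <= 0) or np.any(w <= 0):
            raise InvalidInputError("log-ratio response requires positive growth values")
        return np.log(w / c)
    if mode == "ratio":
        if np.any(c <= 0):
            raise InvalidInputError("ratio response requires positive control growth")
        return w / c
    if mode == "difference":
        return w - c
    raise InvalidInputError(f"unknown response mode '{mode}'")


def vpd_effect_regression(effects, dvpd, alpha: float = 0.05) -> RegressionResult:
    """OLS of per-site growth response on per-site VPD increase.

    The headline question is whether the slope differs from zero; a CI
    covering zero is the neutral-effect outcome.
    """
    import statsmodels.api as sm

    y = np.asarray(effects, dtype=float)
    x = np.asarray(dvpd, dtype=float)
    if y.size != x.size:
        raise AlignmentError("effects and dvpd differ in length")
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise InvalidInputError("need at least 3 sites")
    if np.ptp(x) == 0:
        raise SingularDesignError("dvpd has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=alpha)
    return RegressionResult(slope=float(model.params[1]), se=float(model.bse[1]),
                            p=float(model.pvalues[1]), n=int(y.size),
                            intercept=float(model.params[0]),
                            ci_low=float(ci[1, 0]), ci_high=float(ci[1, 1]))


def analyze_warming_synthesis(table: pd.DataFrame, fit: ExpFit = None,
                              fit_table: pd.DataFrame = None,
                              response_mode: str = "log_ratio") -> dict:
    """End-to-end synthesis-site analysis.

    ``table`` carries one row per site with columns ``ta_c, ta_w, growth_c,
    growth_w`` and optionally ``rh_c/rh_w`` or ``vpd_c/vpd_w``.  The Ta–VPD
    exponential is taken from ``fit`` if given, otherwise fitted (pooled
    across sites) from ``fit_table`` (columns ``ta, vpd``) or from the
    synthesis table's own control/warming (ta, vpd) pairs.  Sites reporting
    RH rather than VPD get VPD via the saturation-curve formula.

    Returns the fit, the per-site table augmented with ``dvpd`` and
    ``response``, and the cross-site regression.
    """
    tab = table.copy()
    for trt in ("c", "w"):
        vcol, rcol = f"vpd_{trt}", f"rh_{trt}"
        if vcol not in tab.columns:
            if rcol not in tab.columns:
                raise InvalidInputError(f"need '{vcol}' or '{rcol}' in the synthesis table")
            tab[vcol] = metphys.vpd_from_rh(tab[f"ta_{trt}"].to_numpy(),
                                            tab[rcol].to_numpy())
    if fit is None:
        if fit_table is not None:
            fit = fit_ta_vpd_exponential(fit_table["ta"], fit_table["vpd"])
        else:
            ta_all = np.concatenate([tab["ta_c"], tab["ta_w"]])
            vpd_all = np.concatenate([tab["vpd_c"], tab["vpd_w"]])
            fit = fit_ta_vpd_exponential(ta_all, vpd_all)
    tab["dvpd"] = simulate_vpd_delta(fit, tab["ta_c"].to_numpy(), tab["ta_w"].to_numpy())
    tab["response"] = growth_response(tab["growth_c"].to_numpy(),
                                      tab["growth_w"].to_numpy(), mode=response_mode)
    reg = vpd_effect_regression(tab["response"], tab["dvpd"])
    return {"fit": fit, "table": tab, "regression": reg}
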