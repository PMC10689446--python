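"""Serial two-mediator mediation models.

Quantifies how water availability (VWC, CWD) and soil hydraulic properties
(SOC, BD) act on the VPD effect (the GPP-vs-VPD partial correlation) through
plant water-use strategy: M1 = uWUE and M2 = the transpiration-vs-VPD
partial correlation, in a serial X -> M1 -> M2 -> Y chain.

All variables are z-standardized internally so every path is a standardized
coefficient.  Three OLS regressions define the paths::

    M1 ~ X              -> a1
    M2 ~ X + M1         -> a2, d21
    Y  ~ X + M1 + M2    -> c', b1, b2

Indirect effects are products of paths (a1*b1, a2*b2, a1*d21*b2) and the
total effect decomposes exactly as c = c' + a1*b1 + a2*b2 + a1*d21*b2 (an
OLS identity on a common sample).  Uncertainty comes from a seeded
percentile bootstrap over rows (default 5,000 resamples); an effect is
"significant" when its bootstrap CI excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, SingularDesignError

__all__ = ["SerialMediation", "SerialMediationResults", "mediation_battery",
           "EFFECT_NAMES"]

PATH_NAMES = ("a1", "a2", "d21", "b1", "b2", "c_prime", "c_total")
EFFECT_NAMES = PATH_NAMES + ("ind_m1", "ind_m2", "ind_serial")


def _ols_coefs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for a design with a leading intercept."""
    XtX = X.T @ X
    try:
        return np.linalg.solve(XtX, X.T @ y)
    except np.linalg.LinAlgError as e:
        raise SingularDesignError("collinear mediation design") from e


def _paths(x, m1, m2, y) -> np.ndarray:
    """All seven standardized paths from the three mediation regressions
    plus the total-effect regression, as [a1,a2,d21,b1,b2,c_prime,c_total]."""
    n = x.size
    one = np.ones(n)
    a1 = _ols_coefs(np.column_stack([one, x]), m1)[1]
    a2, d21 = _ols_coefs(np.column_stack([one, x, m1]), m2)[1:]
    c_prime, b1, b2 = _ols_coefs(np.column_stack([one, x, m1, m2]), y)[1:]
    c_total = _ols_coefs(np.column_stack([one, x]), y)[1]
    return np.array([a1, a2, d21, b1, b2, c_prime, c_total])


def _effects_from_paths(p: np.ndarray) -> np.ndarray:
    a1, a2, d21, b1, b2, c_prime, c_total = p
    return np.concatenate([p, [a1 * b1, a2 * b2, a1 * d21 * b2]])


class SerialMediation:
    """Serial two-mediator mediation model X -> M1 -> M2 -> Y.

    Inputs are 1-d series of equal length (n >= 10); they are z-standardized
    internally, so results are standardized effects and invariant to any
    positive rescaling of the inputs.
    """

    def __init__(self, x, m1, m2, y, names: Optional[Dict[str, str]] = None):
        arrs = {k: np.asarray(v, dtype=float) for k, v in
                zip(("x", "m1", "m2", "y"), (x, m1, m2, y))}
        n = arrs["x"].size
        if any(a.size != n for a in arrs.values()):
            raise InvalidInputError("x, m1, m2, y must have equal lengths")
        stack = np.column_stack(list(arrs.values()))
        ok = np.all(np.isfinite(stack), axis=1)
        stack = stack[ok]
        if stack.shape[0] < 10:
            raise InvalidInputError("need at least 10 complete rows")
        sd = stack.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise SingularDesignError("a variable is constant")
        self._z = (stack - stack.mean(axis=0)) / sd
        self.n = stack.shape[0]
        self.names = {"x": "X", "m1": "M1", "m2": "M2", "y": "Y", **(names or {})}

    def fit(self, n_boot: int = 5000, seed: Optional[int] = None,
            alpha: float = 0.05) -> "SerialMediationResults":
        """Estimate paths and bootstrap their sampling distributions."""
        if n_boot < 200:
            warnings.warn("n_boot < 200 gives unstable percentile intervals",
                          stacklevel=2)
        x, m1, m2, y = self._z.T
        point = _effects_from_paths(_paths(x, m1, m2, y))
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, len(EFFECT_NAMES)))
        n = self.n
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[b] = _effects_from_paths(_paths(x[idx], m1[idx], m2[idx], y[idx]))
        lo = np.percentile(boots, 100 * alpha / 2, axis=0)
        hi = np.percentile(boots, 100 * (1 - alpha / 2), axis=0)
        se = boots.std(axis=0, ddof=1)
        return SerialMediationResults(
            estimates=pd.Series(point, index=EFFECT_NAMES),
            se=pd.Series(se, index=EFFECT_NAMES),
            ci=pd.DataFrame({"low": lo, "high": hi}, index=EFFECT_NAMES),
            n=self.n, n_boot=n_boot, alpha=alpha, names=self.names, seed=seed)


@dataclass
class SerialMediationResults:
    """Standardized paths, indirect effects and percentile-bootstrap intervals."""

    estimates: pd.Series
    se: pd.Series
    ci: pd.DataFrame
    n: int
    n_boot: int
    alpha: float
    names: Dict[str, str]
    seed: Optional[int] = None

    def __getattr__(self, item):
        est = object.__getattribute__(self, "estimates")
        if item in est.index:
            return float(est[item])
        raise AttributeError(item)

    @property
    def significant(self) -> pd.Series:
        """True where the bootstrap CI excludes zero."""
        return (self.ci["low"] > 0) | (self.ci["high"] < 0)

    def conf_int(self) -> pd.DataFrame:
        return self.ci.copy()

    @property
    def decomposition_gap(self) -> float:
        """c_total - (c_prime + ind_m1 + ind_m2 + ind_serial); ~0 by OLS algebra."""
        e = self.estimates
        return float(e["c_total"] - (e["c_prime"] + e["ind_m1"] + e["ind_m2"]
                                     + e["ind_serial"]))

    def summary(self) -> str:
        nm = self.names
        header = (f"Serial mediation: {nm['x']} -> {nm['m1']} -> {nm['m2']} -> {nm['y']}"
                  f"   (n={self.n}, {self.n_boot} bootstrap resamples)")
        rows = [header, f"{'effect':<12}{'estimate':>10}{'se':>9}"
                        f"{'ci_low':>9}{'ci_high':>9}  sig"]
        for k in EFFECT_NAMES:
            star = "*" if self.significant[k] else " "
            rows.append(f"{k:<12}{self.estimates[k]:>10.4f}{self.se[k]:>9.4f}"
                        f"{self.ci.loc[k, 'low']:>9.4f}{self.ci.loc[k, 'high']:>9.4f}  {star}")
        return "\n".join(rows)

    def plot(self, ax=None):
        """Point estimates with bootstrap CIs for the direct and indirect effects."""
        import matplotlib.pyplot as plt
        keys = ["c_prime", "ind_m1", "ind_m2", "ind_serial", "c_total"]
        if ax is None:
            _, ax = plt.subplots()
        est = self.estimates[keys]
        err = np.abs(self.ci.loc[keys].to_numpy().T - est.to_numpy())
        ax.errorbar(keys, est, yerr=err, fmt="o", capsize=4)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("standardized effect")
        return ax


def mediation_battery(table: pd.DataFrame, x_cols: Sequence[str] = ("vwc", "cwd", "soc", "bd"),
                      m1: str = "uwue", m2: str = "pcor_et_vpd",
                      y: str = "pcor_gpp_vpd", n_boot: int = 5000,
                      seed: Optional[int] = None) -> Dict[str, SerialMediationResults]:
    """One serial mediation per exposure column, shared mediators and sample.

    Rows with any missing value in the union of used columns are dropped so
    every exposure is fitted on the same sample.  Seeds for the per-exposure
    bootstraps are derived deterministically from ``seed``.
    """
    cols = list(x_cols) + [m1, m2, y]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise InvalidInputError(f"table lacks columns: {missing}")
    clean = table[cols].dropna().reset_index(drop=True)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(x_cols)) % (2 ** 31)
    out = {}
    for xc, s in zip(x_cols, child_seeds):
        model = SerialMediation(clean[xc], clean[m1], clean[m2], clean[y],
                                names={"x": xc, "m1": m1, "m2": m2, "y": y})
        out[xc] = model.fit(n_boot=n_boot, seed=int(s))
    return out
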