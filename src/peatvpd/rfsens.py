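"""Random-forest perturbation sensitivity of the VPD effect.

A random-forest regression relates the pixel-level partial correlation of
GPP with VPD (the "VPD effect") to six predictors: available volumetric
water content (VWC, %), climate water deficit (CWD, mm), soil organic carbon
(SOC, %), bulk density (BD, g cm-3), underlying water-use efficiency (uWUE)
and the partial correlation of transpiration with VPD.  Predictors are
z-score normalized before training; 60% of rows train the forest and the
held-out 40% provide a validation Pearson r, which must exceed 0.8 before
sensitivities are reported.

Sensitivity of the response to a predictor: perturb that (normalized)
predictor by +1 standard deviation, re-predict with the fitted forest, and
divide the mean prediction change by the standard deviation of the raw
(un-normalized) response; the procedure is repeated 15 times over bootstrap
resamples of the prediction rows and the median is reported.  The statistic
is dimensionless and invariant to rescaling the response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (DegenerateFitError, InvalidInputError, ModelGateError)

logger = logging.getLogger(__name__)

__all__ = ["SensitivityForest", "SensitivityForestResults", "DEFAULT_PREDICTORS"]

DEFAULT_PREDICTORS = ("vwc", "cwd", "soc", "bd", "uwue", "pcor_et_vpd")


class SensitivityForest:
    """Random-forest model of a pixel-level response with perturbation sensitivities.

    Parameters
    ----------
    table : DataFrame with one row per pixel; rows with any missing value in
        the used columns are dropped (listwise) with a logged count.
    response : name of the response column (the GPP-vs-VPD partial correlation).
    predictors : predictor column names; default the six-trait set.
    n_trees : forest size (default 500).
    test_size : held-out validation fraction (default 0.4, i.e. a 60/40 split).
    n_repeats : bootstrap repeats for each sensitivity (default 15).
    gate_r : minimum held-out Pearson r required before sensitivities are
        reported (default 0.8).
    """

    def __init__(self, table: pd.DataFrame, response: str,
                 predictors: Optional[Sequence[str]] = None, n_trees: int = 500,
                 test_size: float = 0.4, n_repeats: int = 15, gate_r: float = 0.8):
        self.response = response
        self.predictors = list(predictors) if predictors is not None else [
            c for c in table.columns if c != response]
        missing = [c for c in self.predictors + [response] if c not in table.columns]
        if missing:
            raise InvalidInputError(f"table lacks columns: {missing}")
        used = table[self.predictors + [response]]
        clean = used.dropna()
        n_dropped = len(used) - len(clean)
        if n_dropped:
            logger.warning("SensitivityForest: dropped %d rows with missing values", n_dropped)
        if len(clean) < 100:
            raise InvalidInputError("need at least 100 complete rows for a meaningful split")
        self.table = clean.reset_index(drop=True)
        self.n_trees = n_trees
        self.test_size = test_size
        self.n_repeats = n_repeats
        self.gate_r = gate_r

    def fit(self, seed: Optional[int] = None) -> "SensitivityForestResults":
        """Train the forest on a seeded 60/40 split and validate on the held-out part."""
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.model_selection import train_test_split

        y = self.table[self.response].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise DegenerateFitError("response is constant")
        X = self.table[self.predictors].to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [p for p, s in zip(self.predictors, sd) if s == 0]
            raise DegenerateFitError(f"constant predictors: {bad}")
        Z = (X - mu) / sd

        ss = np.random.SeedSequence(seed)
        split_seed, forest_seed = [int(s) for s in ss.generate_state(2) % (2 ** 31)]
        Z_tr, Z_te, y_tr, y_te = train_test_split(
            Z, y, test_size=self.test_size, random_state=split_seed)
        model = RandomForestRegressor(n_estimators=self.n_trees,
                                      random_state=forest_seed, n_jobs=1)
        model.fit(Z_tr, y_tr)
        pred = model.predict(Z_te)
        model_r = float(stats.pearsonr(pred, y_te)[0]) if np.std(pred) > 0 else 0.0
        return SensitivityForestResults(
            model=model, Z=Z, y=y, mu=mu, sd=sd, predictors=self.predictors,
            response=self.response, model_r=model_r, n_repeats=self.n_repeats,
            gate_r=self.gate_r, seed=seed)


@dataclass
class SensitivityForestResults:
    """Fitted forest with validation skill and perturbation sensitivities."""

    model: object
    Z: np.ndarray
    y: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    predictors: list
    response: str
    model_r: float
    n_repeats: int = 15
    gate_r: float = 0.8
    seed: Optional[int] = None

    def _check_gate(self, force):
        if not force and not (self.model_r > self.gate_r):
            raise ModelGateError(
                f"held-out r = {self.model_r:.3f} does not exceed the "
                f"{self.gate_r} gate; pass force=True to override")

    def _rng_for(self, predictor_idx: int):
        ss = np.random.SeedSequence(self.seed, spawn_key=(predictor_idx,))
        return np.random.default_rng(ss)

    def sensitivity(self, predictor: str, force: bool = False,
                    direction: str = "plus") -> float:
        """Median perturbation sensitivity for one predictor.

        ``direction='plus'`` perturbs by +1 normalized SD (default);
        ``'symmetric'`` averages the +1 and -(-1) responses.
        """
        self._check_gate(force)
        if predictor not in self.predictors:
            raise InvalidInputError(f"unknown predictor '{predictor}'")
        if direction not in ("plus", "symmetric"):
            raise InvalidInputError(f"unknown direction '{direction}'")
        j = self.predictors.index(predictor)
        rng = self._rng_for(j)
        n = self.Z.shape[0]
        R = self.n_repeats
        sd_y = float(np.std(self.y, ddof=1))
        # all bootstrap repeats predicted in one batched call per perturbation
        idx = rng.integers(0, n, (R, n))
        Zb = self.Z[idx.ravel()]
        base = self.model.predict(Zb).reshape(R, n).mean(axis=1)
        Zp = Zb.copy()
        Zp[:, j] += 1.0
        up = self.model.predict(Zp).reshape(R, n).mean(axis=1)
        if direction == "plus":
            vals = (up - base) / sd_y
        else:
            Zm = Zb.copy()
            Zm[:, j] -= 1.0
            down = self.model.predict(Zm).reshape(R, n).mean(axis=1)
            vals = (up - down) / (2.0 * sd_y)
        return float(np.median(vals))

    def sensitivities(self, force: bool = False, direction: str = "plus") -> pd.Series:
        """Sensitivities for every predictor (a named Series)."""
        return pd.Series({p: self.sensitivity(p, force=force, direction=direction)
                          for p in self.predictors}, name="sensitivity")

    def profile(self, predictor: str, grid=None, n_points: int = 25,
                force: bool = False) -> pd.DataFrame:
        """Partial-dependence-style response curve over a predictor grid.

        The predictor column is set to each raw-scale grid value (normalized
        internally) for every row and the mean forest prediction recorded.
        Grid values outside the observed range trigger an extrapolation
        warning.
        """
        self._check_gate(force)
        if predictor not in self.predictors:
            raise InvalidInputError(f"unknown predictor '{predictor}'")
        j = self.predictors.index(predictor)
        raw = self.Z[:, j] * self.sd[j] + self.mu[j]
        lo, hi = raw.min(), raw.max()
        if grid is None:
            grid = np.linspace(lo, hi, n_points)
        grid = np.asarray(grid, dtype=float)
        if np.any(grid < lo) or np.any(grid > hi):
            warnings.warn("profile grid extends beyond the observed predictor range "
                          "(extrapolation)", stacklevel=2)
        preds = []
        for g in grid:
            Zg = self.Z.copy()
            Zg[:, j] = (g - self.mu[j]) / self.sd[j]
            preds.append(float(self.model.predict(Zg).mean()))
        return pd.DataFrame({predictor: grid, "prediction": preds})

    def summary(self) -> str:
        lines = [
            "Random-forest perturbation sensitivity",
            f"  response      : {self.response}",
            f"  held-out r    : {self.model_r:.3f} (gate > {self.gate_r})",
            f"  repeats       : {self.n_repeats} (bootstrap rows, fixed model)",
        ]
        if self.model_r > self.gate_r:
            sens = self.sensitivities()
            for p, v in sens.items():
                lines.append(f"  {p:<14s}: {v:+.3f}")
        else:
            lines.append("  sensitivities withheld: validation gate not passed")
        return "\n".join(lines)

    def plot(self, ax=None, force: bool = False):
        """Bar chart of the per-predictor sensitivities."""
        import matplotlib.pyplot as plt
        sens = self.sensitivities(force=force)
        if ax is None:
            _, ax = plt.subplots()
        colors = ["tab:blue" if v >= 0 else "tab:brown" for v in sens]
        ax.bar(sens.index, sens.values, color=colors)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("sensitivity of " + self.response)
        ax.tick_params(axis="x", rotation=45)
        return ax
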