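"""Logit-method ICx estimation from dose-viability tables.

The logit method regresses logit(viability) on log10(dose) by ordinary least
squares and reads ICx off the fitted line: ICx is the dose giving x%
inhibition, i.e. fitted viability 1 - x/100 (IC50 -> viability 0.5, IC30 ->
viability 0.7, so IC30 < IC50 on a decreasing curve). Viability values are
clipped to [0.01, 0.99] before the logit transform; clipped points are kept
in the fit and flagged rather than dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["LogitDoseResponse", "fit_logit", "predict_viability"]


class LogitDoseResponse(BaseEstimator, RegressorMixin):
    """Logit-linear dose-response fit.

    Parameters
    ----------
    clip : (float, float), default (0.01, 0.99)
        Viability bounds applied before the logit transform. Points at or
        beyond a bound are moved to it (and recorded), not excluded.

    Attributes
    ----------
    slope_, intercept_ : coefficients of logit(v) = intercept + slope*log10(d).
    ic50_ : dose at fitted viability 0.5 (= 10**(-intercept/slope)).
    ic30_ : dose at 30% inhibition (fitted viability 0.7).
    r_squared_, residual_sd_, n_points_ : fit diagnostics.
    clipped_points_ : DataFrame of points moved to a clip bound.
    """

    def __init__(self, clip: tuple[float, float] = (0.01, 0.99)):
        self.clip = clip

    def fit(self, doses, viability) -> "LogitDoseResponse":
        d = np.asarray(doses, dtype=float).ravel()
        v = np.asarray(viability, dtype=float).ravel()
        if d.shape != v.shape:
            raise ValueError("doses and viability must have equal length")
        if np.any(~np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("doses must be positive and finite")
        if np.any(~np.isfinite(v)):
            raise ValueError("viability values must be finite")
        lo, hi = self.clip
        clipped_mask = (v <= lo) | (v >= hi)
        vc = np.clip(v, lo, hi)
        if np.unique(d).size < 3:
            raise ValueError("need at least 3 distinct doses for a logit fit")

        x = np.log10(d)
        y = logit(vc)
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        self.intercept_, self.slope_ = float(coef[0]), float(coef[1])
        if self.slope_ == 0:
            raise ValueError("degenerate fit: zero slope, ICx undefined")

        resid = y - X @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = max(len(y) - 2, 1)
        self.residual_sd_ = float(np.sqrt(ss_res / dof))
        self.n_points_ = int(len(y))
        self.clipped_points_ = pd.DataFrame({
            "dose": d[clipped_mask], "viability": v[clipped_mask],
            "clipped_to": vc[clipped_mask]})
        self.ic50_ = self.ic(50.0)
        self.ic30_ = self.ic(30.0)
        return self

    def ic(self, inhibition_percent: float) -> float:
        """Dose producing the given % inhibition (viability 1 - x/100)."""
        if not 0.0 < inhibition_percent < 100.0:
            raise ValueError("inhibition percent must be in (0, 100)")
        target = logit(1.0 - inhibition_percent / 100.0)
        return float(10.0 ** ((target - self.intercept_) / self.slope_))

    def predict(self, doses) -> np.ndarray:
        """Fitted viability at the given doses (inverse-logit of the line)."""
        d = np.asarray(doses, dtype=float)
        if np.any(d <= 0):
            raise ValueError("doses must be positive")
        return expit(self.intercept_ + self.slope_ * np.log10(d))

    def summary(self) -> dict:
        return {"slope": self.slope_, "intercept": self.intercept_,
                "ic50": self.ic50_, "ic30": self.ic30_,
                "r_squared": self.r_squared_,
                "residual_sd": self.residual_sd_,
                "n_points": self.n_points_,
                "n_clipped": int(len(self.clipped_points_))}


def fit_logit(doses, viability,
              clip: tuple[float, float] = (0.01, 0.99)) -> LogitDoseResponse:
    """Fit the logit-linear model; convenience wrapper."""
    return LogitDoseResponse(clip=clip).fit(doses, viability)


def predict_viability(fit: LogitDoseResponse, dose) -> np.ndarray:
    return fit.predict(dose)
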