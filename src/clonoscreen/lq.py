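"""Clonogenic surviving fractions and linear-quadratic survival fitting.

SF(D) = exp(-(alpha*D + beta*D**2)) is the standard model of clonogenic
survival after radiation dose D (Gy): alpha (Gy^-1) captures single-track
lethal damage, beta (Gy^-2) the quadratic inter-track component. The fit is
performed in log-survival space, ln SF = -alpha*D - beta*D**2, as
nonnegative least squares, so alpha, beta >= 0 and SF is non-increasing in
dose by construction. SF = 0 points (no colonies) cannot enter a log fit;
they are excluded and reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "surviving_fraction",
    "LinearQuadraticModel",
    "fit_lq",
    "enhancement_ratio",
    "analyze_clonogenic",
]


def surviving_fraction(colonies: float, seeded: float,
                       pe_control: float) -> float:
    """SF = colonies / (seeded * control plating efficiency)."""
    if seeded <= 0:
        raise ValueError("seeded cell number must be positive")
    if not 0.0 < pe_control <= 1.0:
        raise ValueError("plating efficiency must lie in (0, 1]")
    if colonies < 0:
        raise ValueError("colony count must be nonnegative")
    return colonies / (seeded * pe_control)


class LinearQuadraticModel(BaseEstimator, RegressorMixin):
    """Linear-quadratic survival-curve fit with alpha, beta >= 0.

    Replicate SFs are averaged per dose before fitting (optionally weighted).
    The dose-0 point anchors SF(0) = 1 exactly (the model has no intercept).

    Attributes
    ----------
    alpha_ : Gy^-1 linear kill coefficient.
    beta_ : Gy^-2 quadratic kill coefficient.
    cov_ : 2x2 covariance of (alpha, beta) from the unconstrained
        least-squares linearization (reported as NaN when a coefficient sits
        on the zero boundary).
    sf_table_ : per-dose (dose, sf, n) table actually fitted.
    excluded_ : DataFrame of zero-SF doses excluded from the log fit.
    """

    def __init__(self):
        pass

    def fit(self, doses, sf) -> "LinearQuadraticModel":
        d = np.asarray(doses, dtype=float).ravel()
        s = np.asarray(sf, dtype=float).ravel()
        if d.shape != s.shape:
            raise ValueError("doses and sf must have equal length")
        if np.any(s < 0) or np.any(s > 1.0 + 1e-12):
            raise ValueError("surviving fractions must lie in [0, 1]")
        # average replicates per dose first
        tab = pd.DataFrame({"dose": d, "sf": s}).groupby(
            "dose", as_index=False).agg(sf=("sf", "mean"), n=("sf", "size"))
        if 0.0 not in tab["dose"].values:
            raise ValueError("a dose-0 (control) point is required")
        usable = tab[tab["sf"] > 0].reset_index(drop=True)
        self.excluded_ = tab[tab["sf"] <= 0].reset_index(drop=True)
        if len(usable) < 3:
            raise ValueError("need >= 3 positive-SF doses (including 0)")

        dd = usable["dose"].to_numpy()
        y = -np.log(usable["sf"].to_numpy())  # alpha*D + beta*D^2
        X = np.column_stack([dd, dd * dd])
        coef, _ = nnls(X, y)
        self.alpha_, self.beta_ = float(coef[0]), float(coef[1])

        resid = y - X @ coef
        dof = max(len(y) - 2, 1)
        s2 = float(resid @ resid) / dof
        on_boundary = (self.alpha_ == 0.0) or (self.beta_ == 0.0)
        xtx = X.T @ X
        if on_boundary or np.linalg.matrix_rank(xtx) < 2:
            self.cov_ = np.full((2, 2), np.nan)
        else:
            self.cov_ = s2 * np.linalg.inv(xtx)
        self.sf_table_ = usable
        return self

    def predict(self, doses) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        return np.exp(-(self.alpha_ * d + self.beta_ * d * d))

    def dose_for_survival(self, survival_level: float) -> float:
        """Dose at which the fitted curve crosses the given SF.

        Solves alpha*D + beta*D^2 = -ln S for the positive root.
        """
        if not 0.0 < survival_level < 1.0:
            raise ValueError("survival level must lie in (0, 1)")
        k = -np.log(survival_level)
        a, b = self.alpha_, self.beta_
        if a == 0.0 and b == 0.0:
            raise ValueError("flat survival curve: level unreachable")
        if b == 0.0:
            return k / a
        # stable form of the positive quadratic root (no cancellation
        # when 4*b*k << a^2)
        return float(2.0 * k / (a + np.sqrt(a * a + 4.0 * b * k)))

    def summary(self) -> dict:
        return {"alpha": self.alpha_, "beta": self.beta_,
                "cov": self.cov_.tolist(),
                "n_excluded_zero_sf": int(len(self.excluded_))}


def fit_lq(doses, sf) -> LinearQuadraticModel:
    """Fit SF(D) = exp(-alpha*D - beta*D^2); convenience wrapper."""
    return LinearQuadraticModel().fit(doses, sf)


def enhancement_ratio(control: LinearQuadraticModel,
                      treated: LinearQuadraticModel,
                      survival_level: float = 0.1) -> float:
    """Sensitizer enhancement ratio at an iso-survival level.

    SER = D_control(S) / D_treated(S): how much less dose is needed with the
    sensitizer on board to reach the same survival. Identical fits give 1;
    doubling both alpha and beta gives exactly 2 at every level.
    """
    return (control.dose_for_survival(survival_level)
            / treated.dose_for_survival(survival_level))


def analyze_clonogenic(table: pd.DataFrame,
                       normalize_drug_alone: bool = True,
                       ) -> dict[str, LinearQuadraticModel]:
    """Fit an LQ curve per arm from a (dose, replicate, seeded, colonies, arm)
    table.

    The arm named ``control`` (radiation only, vehicle) supplies the plating
    efficiency at dose 0. When ``normalize_drug_alone`` is True (standard
    practice for drug+IR combinations), each non-control arm is normalized by
    its *own* dose-0 plating efficiency, so the curve isolates the radiation
    response on top of drug-alone toxicity; with False every arm uses the
    control PE.
    """
    required = {"dose", "seeded", "colonies", "arm"}
    if not required.issubset(table.columns):
        raise ValueError(f"clonogenic table needs columns {sorted(required)}")
    fits: dict[str, LinearQuadraticModel] = {}

    def _pe(arm_df: pd.DataFrame) -> float:
        d0 = arm_df[arm_df["dose"] == 0]
        if len(d0) == 0:
            raise ValueError("each arm needs a dose-0 point for PE")
        return float((d0["colonies"] / d0["seeded"]).mean())

    ctrl = table[table["arm"] == "control"]
    pe_ctrl = _pe(ctrl) if len(ctrl) else None
    for arm, arm_df in table.groupby("arm", sort=True):
        pe = _pe(arm_df) if (normalize_drug_alone or pe_ctrl is None) \
            else pe_ctrl
        sf = [surviving_fraction(r.colonies, r.seeded, pe)
              for r in arm_df.itertuples()]
        fits[arm] = fit_lq(arm_df["dose"].to_numpy(), np.minimum(sf, 1.0))
    return fits
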