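"""Survival-reduction-factor (SRF) screen analysis.

The screening statistic for a drug at concentration x under a fixed
radiation dose (2 Gy in the reference design) is

    SRF = NCN_2Gy * NCN_drug(x) / NCN_2Gy+drug(x)

where each NCN (normalized colony number) is the mean colony count of a
condition divided by the mean colony count of the untreated control on the
same plate. SRF = 1 under multiplicative independence of drug and radiation
kill; SRF >= 1.5 flags a concentration as radiosensitizing. Replicate counts
are averaged *before* ratios are taken.

Concentrations where the drug-only or combination arm forms too few colonies
(mean below ``min_mean``, or a zero combination mean) are flagged
undetectable and excluded from hit-fraction denominators — the analogue of a
screen reporting "SRF value unavailable" for fully cytotoxic concentrations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "classify_condition",
    "normalize_counts",
    "compute_srf",
    "assess_detectability",
    "hit_fraction",
    "rank_screen",
    "SrfScreen",
]

_REQUIRED_COLS = ("plate_id", "drug_id", "concentration", "radiation_dose",
                  "replicate", "colony_count")


def classify_condition(concentration, radiation_dose) -> str:
    """One of 'control', 'drug', 'ir', 'combo' for a well."""
    has_drug = np.isfinite(concentration)
    irradiated = radiation_dose > 0
    if has_drug and irradiated:
        return "combo"
    if has_drug:
        return "drug"
    if irradiated:
        return "ir"
    return "control"


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLS if c not in records.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")
    if (records["colony_count"] < 0).any():
        raise ValueError("colony counts must be nonnegative")
    return records


def normalize_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Compute NCNs per (plate, drug, concentration).

    Controls are matched within each plate; a plate without control wells
    (or with a zero control mean) is a hard error since normalization is
    impossible. Returns one row per (plate_id, drug_id, concentration) with
    columns ``ncn_2gy, ncn_drug, ncn_combo``, the underlying condition means
    (``mean_control, mean_ir, mean_drug, mean_combo``) and replicate counts.
    """
    records = _validate(records)
    cond = [classify_condition(c, d) for c, d in
            zip(records["concentration"], records["radiation_dose"])]
    records = records.assign(_cond=cond)

    out = []
    for plate, plate_df in records.groupby("plate_id", sort=False):
        ctrl = plate_df[plate_df["_cond"] == "control"]["colony_count"]
        if len(ctrl) == 0:
            raise ValueError(f"plate {plate!r}: no control wells; "
                             "cross-plate normalization is refused")
        m_ctrl = ctrl.mean()
        if m_ctrl <= 0:
            raise ValueError(f"plate {plate!r}: control mean is zero; "
                             "normalization impossible")
        ir = plate_df[plate_df["_cond"] == "ir"]["colony_count"]
        if len(ir) == 0:
            raise ValueError(f"plate {plate!r}: no radiation-only wells")
        m_ir = ir.mean()

        treated = plate_df[plate_df["_cond"].isin(["drug", "combo"])]
        for (drug, conc), grp in treated.groupby(
                ["drug_id", "concentration"], sort=False):
            d = grp[grp["_cond"] == "drug"]["colony_count"]
            c = grp[grp["_cond"] == "combo"]["colony_count"]
            out.append({
                "plate_id": plate, "drug_id": drug, "concentration": conc,
                "mean_control": m_ctrl, "mean_ir": m_ir,
                "mean_drug": d.mean() if len(d) else np.nan,
                "mean_combo": c.mean() if len(c) else np.nan,
                "n_control": len(ctrl), "n_ir": len(ir),
                "n_drug": len(d), "n_combo": len(c),
                "ncn_2gy": m_ir / m_ctrl,
                "ncn_drug": d.mean() / m_ctrl if len(d) else np.nan,
                "ncn_combo": c.mean() / m_ctrl if len(c) else np.nan,
            })
    return pd.DataFrame(out)


def compute_srf(ncn_2gy: float, ncn_drug: float, ncn_combo: float) -> float:
    """SRF = NCN_2Gy * NCN_drug / NCN_combo; NaN when the combo NCN is 0."""
    if not np.isfinite(ncn_combo) or ncn_combo == 0:
        return np.nan
    return ncn_2gy * ncn_drug / ncn_combo


def assess_detectability(mean_drug: float, mean_combo: float,
                         min_mean: float = 3.0) -> bool:
    """A concentration is detectable when both treated arms form colonies.

    Undetectable when the drug-only or combination mean colony count falls
    below ``min_mean`` (default 3 colonies), or the combination mean is 0 —
    the regime where a ratio of near-empty wells carries no information.
    """
    if not (np.isfinite(mean_drug) and np.isfinite(mean_combo)):
        return False
    if mean_combo <= 0:
        return False
    return mean_drug >= min_mean and mean_combo >= min_mean


def hit_fraction(srf: np.ndarray, detectable: np.ndarray,
                 threshold: float = 1.5) -> float:
    """Percent of detectable concentrations with SRF >= threshold.

    Returns NaN when no concentration is detectable (the denominator is the
    empty set).
    """
    srf = np.asarray(srf, dtype=float)
    detectable = np.asarray(detectable, dtype=bool)
    n_det = int(detectable.sum())
    if n_det == 0:
        return np.nan
    hits = int((srf[detectable] >= threshold).sum())
    return 100.0 * hits / n_det


def rank_screen(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Order drugs for reporting and export the SRF heatmap matrix.

    ``profiles`` is the per-(drug, concentration) table produced by
    :class:`SrfScreen` (columns drug_id, concentration, srf, detectable,
    hit_fraction). Drugs sort by hit fraction (descending, NaN last), ties
    broken by mean SRF over detectable entries, then drug_id. The heatmap is
    a (drug x concentration) matrix of SRF with NaN marking undetectable
    cells, rows in rank order.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles to rank")

    def _mean_det_srf(g: pd.DataFrame) -> float:
        det = g[g["detectable"]]
        return det["srf"].mean() if len(det) else np.nan

    rows = []
    for drug, g in profiles.groupby("drug_id", sort=True):
        rows.append({"drug_id": drug,
                     "hit_fraction": g["hit_fraction"].iloc[0],
                     "mean_srf_detectable": _mean_det_srf(g),
                     "n_detectable": int(g["detectable"].sum())})
    ranking = pd.DataFrame(rows)
    ranking = ranking.sort_values(
        by=["hit_fraction", "mean_srf_detectable", "drug_id"],
        ascending=[False, False, True], na_position="last",
        kind="mergesort").reset_index(drop=True)
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))

    heat = profiles.pivot_table(index="drug_id", columns="concentration",
                                values="srf", aggfunc="mean")
    heat = heat.reindex(ranking["drug_id"])
    heat = heat[sorted(heat.columns, reverse=True)]
    return ranking, heat


class SrfScreen(BaseEstimator):
    """Full SRF screen pipeline over a long-format well table.

    Parameters
    ----------
    hit_threshold : float, default 1.5
        SRF at or above this classifies a concentration as radiosensitizing.
    min_mean : float, default 3.0
        Detectability floor on the drug-only and combination mean counts.
    n_bootstrap : int, default 0
        When positive, attach a percentile bootstrap CI (over replicate
        wells) to each SRF. Off by default.
    ci_level : float, default 0.95
    random_state : int, default 0
        Seed for the bootstrap resampler.

    Attributes
    ----------
    ncn_table_ : DataFrame of NCNs per (plate, drug, concentration).
    profiles_ : DataFrame with srf, detectable, hit flag and hit_fraction.
    hit_fractions_ : Series of hit fraction (%) per drug.
    ranking_ : DataFrame of drugs in rank order.
    heatmap_ : DataFrame, SRF matrix (drug x concentration).
    """

    def __init__(self, hit_threshold: float = 1.5, min_mean: float = 3.0,
                 n_bootstrap: int = 0, ci_level: float = 0.95,
                 random_state: int = 0):
        self.hit_threshold = hit_threshold
        self.min_mean = min_mean
        self.n_bootstrap = n_bootstrap
        self.ci_level = ci_level
        self.random_state = random_state

    def fit(self, records: pd.DataFrame, y=None) -> "SrfScreen":
        ncn = normalize_counts(records)
        srf = np.array([compute_srf(r.ncn_2gy, r.ncn_drug, r.ncn_combo)
                        for r in ncn.itertuples()])
        det = np.array([assess_detectability(r.mean_drug, r.mean_combo,
                                             self.min_mean)
                        for r in ncn.itertuples()])
        prof = ncn.copy()
        prof["srf"] = np.where(det, srf, np.nan)
        prof["detectable"] = det
        prof["hit"] = det & (prof["srf"] >= self.hit_threshold)

        hf = prof.groupby("drug_id")[["srf", "detectable"]].apply(
            lambda g: hit_fraction(g["srf"].to_numpy(),
                                   g["detectable"].to_numpy(),
                                   self.hit_threshold))
        prof = prof.merge(hf.rename("hit_fraction"), on="drug_id")

        if self.n_bootstrap > 0:
            lo, hi = self._bootstrap_ci(records, prof)
            prof["srf_ci_low"] = lo
            prof["srf_ci_high"] = hi

        self.ncn_table_ = ncn
        self.profiles_ = prof
        self.hit_fractions_ = hf
        self.ranking_, self.heatmap_ = rank_screen(prof)
        return self

    def _bootstrap_ci(self, records: pd.DataFrame, prof: pd.DataFrame):
        rng = np.random.default_rng(self.random_state)
        alpha = 1.0 - self.ci_level
        cond = [classify_condition(c, d) for c, d in
                zip(records["concentration"], records["radiation_dose"])]
        rec = records.assign(_cond=cond)
        lows, highs = [], []
        for r in prof.itertuples():
            plate = rec[rec["plate_id"] == r.plate_id]
            arms = {
                "control": plate[plate["_cond"] == "control"][
                    "colony_count"].to_numpy(),
                "ir": plate[plate["_cond"] == "ir"]["colony_count"].to_numpy(),
                "drug": plate[(plate["_cond"] == "drug")
                              & (plate["drug_id"] == r.drug_id)
                              & (plate["concentration"] == r.concentration)][
                    "colony_count"].to_numpy(),
                "combo": plate[(plate["_cond"] == "combo")
                               & (plate["drug_id"] == r.drug_id)
                               & (plate["concentration"] == r.concentration)][
                    "colony_count"].to_numpy(),
            }
            if not r.detectable or any(len(v) == 0 for v in arms.values()):
                lows.append(np.nan)
                highs.append(np.nan)
                continue
            stats = []
            for _ in range(self.n_bootstrap):
                m = {k: rng.choice(v, size=len(v), replace=True).mean()
                     for k, v in arms.items()}
                if m["control"] > 0 and m["combo"] > 0:
                    stats.append(m["ir"] * m["drug"]
                                 / (m["combo"] * m["control"]))
            if stats:
                lows.append(float(np.quantile(stats, alpha / 2)))
                highs.append(float(np.quantile(stats, 1 - alpha / 2)))
            else:
                lows.append(np.nan)
                highs.append(np.nan)
        return lows, highs
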