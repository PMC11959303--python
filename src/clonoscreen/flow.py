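"""Flow-cytometry summaries: Annexin/PI quadrant gating and DNA-content
cell-cycle deconvolution.

Apoptosis gating places one cut per channel at the valley between the two
log-intensity modes (negative and positive populations) and partitions the
events into four quadrants: viable (Annexin-/PI-), early apoptotic
(Annexin+/PI-), late apoptotic (Annexin+/PI+) and necrotic (Annexin-/PI+).
The apoptosis rate is the Annexin-positive fraction (early + late) by
default; an ``early_only`` switch restricts it to the early quadrant.

Cell-cycle analysis fits a three-component mixture to the PI (DNA-content)
histogram: a Gaussian G0/G1 peak at the 2N position, a Gaussian G2/M peak
constrained near twice the G1 mean, and an S-phase "bridge" — a uniform
density between the two peak means convolved with the G1 Gaussian width.
Component weights are estimated by EM and reported as phase fractions.
Peaks are located by pairing KDE modes at a ~2x spacing, which stays correct
even when G2/M dominates the histogram (e.g. after a combined drug +
radiation treatment arrests most cells at 4N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde, norm
from sklearn.base import BaseEstimator

__all__ = [
    "valley_threshold",
    "QuadrantGater",
    "apoptosis_rate",
    "CellCycleFractions",
    "CellCycleModel",
    "cell_cycle_fractions",
]


def valley_threshold(values: np.ndarray, grid_size: int = 512) -> float:
    """Cut between the two dominant modes of a log-intensity distribution.

    A Gaussian KDE (Scott bandwidth, scale-equivariant) is evaluated on a
    grid; the threshold is the density minimum between the two highest local
    maxima. Falls back to the midpoint of the data range when the density is
    unimodal.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2 or np.ptp(v) == 0:
        return float(v.mean()) if v.size else np.nan
    kde = gaussian_kde(v)
    pad = 0.05 * np.ptp(v)
    grid = np.linspace(v.min() - pad, v.max() + pad, grid_size)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if len(maxima) < 2:
        return float(0.5 * (v.min() + v.max()))
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    valley = left + int(np.argmin(dens[left:right + 1]))
    return float(grid[valley])


class QuadrantGater(BaseEstimator):
    """Two-channel quadrant gate for Annexin V / PI event tables.

    Parameters
    ----------
    annexin_cut, pi_cut : float or None
        Manual cuts on the raw intensity scale; None places each cut at the
        valley between log10-intensity modes.
    early_only : bool, default False
        Count only the early-apoptotic quadrant in the apoptosis rate.

    Attributes
    ----------
    annexin_cut_, pi_cut_ : cuts actually used (raw intensity scale).
    quadrants_ : DataFrame with one row per quadrant (label, count, fraction).
    apoptosis_rate_ : percent of events counted apoptotic (NaN on an empty
        table).
    labels_ : per-event quadrant labels.
    """

    def __init__(self, annexin_cut: float | None = None,
                 pi_cut: float | None = None, early_only: bool = False):
        self.annexin_cut = annexin_cut
        self.pi_cut = pi_cut
        self.early_only = early_only

    def fit(self, events: pd.DataFrame, y=None) -> "QuadrantGater":
        for ch in ("annexin", "pi"):
            if ch not in events.columns:
                raise ValueError(f"event table missing channel {ch!r}")
        ann = events["annexin"].to_numpy(dtype=float)
        pi = events["pi"].to_numpy(dtype=float)
        if np.any(ann < 0) or np.any(pi < 0):
            raise ValueError("intensities must be nonnegative")

        if len(events) == 0:
            self.annexin_cut_ = self.pi_cut_ = np.nan
            self.quadrants_ = pd.DataFrame(
                {"quadrant": ["viable", "early", "late", "necrotic"],
                 "count": 0, "fraction": np.nan})
            self.apoptosis_rate_ = np.nan
            self.labels_ = np.array([], dtype=object)
            return self

        eps = 1e-12
        self.annexin_cut_ = (self.annexin_cut if self.annexin_cut is not None
                             else 10.0 ** valley_threshold(np.log10(ann + eps)))
        self.pi_cut_ = (self.pi_cut if self.pi_cut is not None
                        else 10.0 ** valley_threshold(np.log10(pi + eps)))

        ann_pos = ann > self.annexin_cut_
        pi_pos = pi > self.pi_cut_
        labels = np.empty(len(events), dtype=object)
        labels[~ann_pos & ~pi_pos] = "viable"
        labels[ann_pos & ~pi_pos] = "early"
        labels[ann_pos & pi_pos] = "late"
        labels[~ann_pos & pi_pos] = "necrotic"
        self.labels_ = labels

        order = ["viable", "early", "late", "necrotic"]
        counts = pd.Series(labels).value_counts().reindex(order, fill_value=0)
        n = len(events)
        self.quadrants_ = pd.DataFrame({"quadrant": order,
                                        "count": counts.to_numpy(),
                                        "fraction": counts.to_numpy() / n})
        apop = counts["early"] if self.early_only \
            else counts["early"] + counts["late"]
        self.apoptosis_rate_ = 100.0 * apop / n
        return self


def apoptosis_rate(events: pd.DataFrame,
                   thresholds: tuple[float, float] | None = None,
                   early_only: bool = False) -> tuple[float, pd.DataFrame]:
    """Percent apoptotic events and the quadrant table."""
    ann_cut, pi_cut = thresholds if thresholds is not None else (None, None)
    g = QuadrantGater(annexin_cut=ann_cut, pi_cut=pi_cut,
                      early_only=early_only).fit(events)
    return g.apoptosis_rate_, g.quadrants_


@dataclass
class CellCycleFractions:
    """Phase fractions from a DNA-content histogram; fractions sum to 1."""

    g0g1: float
    s: float
    g2m: float
    g1_mean: float
    g2_mean: float
    g1_sd: float
    g2_sd: float

    def as_dict(self) -> dict:
        return {"g0g1": self.g0g1, "s": self.s, "g2m": self.g2m,
                "g1_mean": self.g1_mean, "g2_mean": self.g2_mean}


def _bridge_pdf(x: np.ndarray, a: float, b: float, sigma: float) -> np.ndarray:
    """Density of Uniform(a, b) convolved with N(0, sigma)."""
    if sigma <= 0:
        return np.where((x >= a) & (x <= b), 1.0 / (b - a), 0.0)
    return (norm.cdf((x - a) / sigma) - norm.cdf((x - b) / sigma)) / (b - a)


def _kde_modes(x: np.ndarray, grid_size: int = 1024):
    """Grid, density and local-maximum indices of a KDE of x."""
    kde = gaussian_kde(x)
    pad = 0.05 * np.ptp(x)
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    dens = kde(grid)
    modes = argrelextrema(dens, np.greater)[0]
    if len(modes) == 0:
        modes = np.array([int(np.argmax(dens))])
    return grid, dens, modes


def _locate_peaks(x: np.ndarray) -> tuple[float, float]:
    """Find the 2N (G1) and 4N (G2) peak positions by mode pairing.

    Among KDE modes, every pair (m_i, m_j) with m_j within +/-20% of 2*m_i
    is a candidate (G1, G2) pair; the pair with the largest summed density
    wins. With a single usable mode the peak is taken as 2N (G1) — the
    diploid peak is the conventional reference — and G2 is placed at twice
    it.
    """
    grid, dens, modes = _kde_modes(x)
    pos = grid[modes]
    height = dens[modes]
    # drop negligible modes (< 1% of the max) that are KDE ripple
    keep = height >= 0.01 * height.max()
    pos, height = pos[keep], height[keep]

    best, best_mass = None, -np.inf
    for i in range(len(pos)):
        for j in range(len(pos)):
            if pos[j] <= pos[i]:
                continue
            if abs(pos[j] - 2.0 * pos[i]) <= 0.20 * 2.0 * pos[i]:
                mass = height[i] + height[j]
                if mass > best_mass:
                    best, best_mass = (pos[i], pos[j]), mass
    if best is not None:
        return float(best[0]), float(best[1])
    top = float(pos[np.argmax(height)])
    return top, 2.0 * top


class CellCycleModel(BaseEstimator):
    """Three-component mixture fit of a PI DNA-content histogram.

    Components: N(mu1, s1) for G0/G1, N(mu2, s2) for G2/M with mu2
    constrained within ``g2_window`` of 2*mu1, and a uniform-with-Gaussian-
    edges bridge between mu1 and mu2 for S phase. Weights, means and SDs are
    estimated by EM; phase fractions are the converged weights.

    Parameters
    ----------
    min_events : int, default 500
        Fewer events raise an error (too sparse for a stable histogram fit).
    g2_window : float, default 0.15
        The G2 mean may move within +/- this relative window around 2*mu1.
    max_iter, tol : EM controls.
    """

    def __init__(self, min_events: int = 500, g2_window: float = 0.15,
                 max_iter: int = 200, tol: float = 1e-8):
        self.min_events = min_events
        self.g2_window = g2_window
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, dna_content, y=None) -> "CellCycleModel":
        x = np.asarray(dna_content, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size < self.min_events:
            raise ValueError(f"need >= {self.min_events} events "
                             f"(got {x.size})")
        if np.ptp(x) == 0:
            raise ValueError("no discernible peak: all events identical")

        # degenerate noiseless input (delta peaks): classify exactly
        mu1, mu2 = _locate_peaks(x)
        tolr = 1e-9 * max(abs(mu1), 1.0)
        near1 = np.abs(x - mu1) <= tolr
        near2 = np.abs(x - mu2) <= tolr
        if (near1 | near2).mean() > 0.999 and near1.any():
            n = x.size
            self._finalize(near1.mean(), 1.0 - near1.mean() - near2.mean(),
                           near2.mean(), mu1, mu2, 0.0, 0.0, n)
            return self

        self._em(x, mu1, mu2)
        return self

    def _em(self, x: np.ndarray, mu1: float, mu2: float) -> None:
        n = x.size
        s1 = max(np.std(x[np.abs(x - mu1) < 0.1 * mu1]) if
                 np.any(np.abs(x - mu1) < 0.1 * mu1) else 0.05 * mu1,
                 1e-3 * mu1)
        s2 = 2.0 * s1
        w = np.array([1 / 3, 1 / 3, 1 / 3])
        lo2, hi2 = (2 * mu1 * (1 - self.g2_window),
                    2 * mu1 * (1 + self.g2_window))
        prev_ll = -np.inf
        for _ in range(self.max_iter):
            p = np.column_stack([
                w[0] * norm.pdf(x, mu1, s1),
                w[1] * _bridge_pdf(x, mu1, mu2, s1),
                w[2] * norm.pdf(x, mu2, s2),
            ])
            tot = p.sum(axis=1)
            tot[tot == 0] = np.finfo(float).tiny
            ll = float(np.log(tot).sum())
            r = p / tot[:, None]
            w = r.mean(axis=0)
            # M-step for the Gaussian peaks (bridge edges track mu1/mu2)
            if r[:, 0].sum() > 0:
                mu1_new = float((r[:, 0] * x).sum() / r[:, 0].sum())
                # keep G1 within 20% of its initial location
                mu1 = float(np.clip(mu1_new, 0.8 * mu1, 1.2 * mu1))
                s1 = float(np.sqrt((r[:, 0] * (x - mu1) ** 2).sum()
                                   / r[:, 0].sum()))
                s1 = max(s1, 1e-6 * mu1)
            if r[:, 2].sum() > 0:
                mu2_new = float((r[:, 2] * x).sum() / r[:, 2].sum())
                mu2 = float(np.clip(mu2_new, lo2, hi2))
                s2 = float(np.sqrt((r[:, 2] * (x - mu2) ** 2).sum()
                                   / r[:, 2].sum()))
                s2 = max(s2, 1e-6 * mu2)
            if abs(ll - prev_ll) < self.tol * max(abs(ll), 1.0):
                break
            prev_ll = ll
        self._finalize(w[0], w[1], w[2], mu1, mu2, s1, s2, n)

    def _finalize(self, g1, s, g2, mu1, mu2, s1, s2, n) -> None:
        total = g1 + s + g2
        self.fractions_ = CellCycleFractions(
            g0g1=float(g1 / total), s=float(s / total), g2m=float(g2 / total),
            g1_mean=float(mu1), g2_mean=float(mu2),
            g1_sd=float(s1), g2_sd=float(s2))
        self.n_events_ = int(n)

    @property
    def g0g1_(self) -> float:
        return self.fractions_.g0g1

    @property
    def s_(self) -> float:
        return self.fractions_.s

    @property
    def g2m_(self) -> float:
        return self.fractions_.g2m


def cell_cycle_fractions(events: pd.DataFrame | np.ndarray,
                         ) -> CellCycleFractions:
    """Fit the 3-component model and return phase fractions.

    Accepts either a FlowEventTable with a ``dna_content`` column or a bare
    array of DNA-content values.
    """
    if isinstance(events, pd.DataFrame):
        if "dna_content" not in events.columns:
            raise ValueError("event table missing 'dna_content' column")
        x = events["dna_content"].to_numpy()
    else:
        x = np.asarray(events)
    return CellCycleModel().fit(x).fractions_
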