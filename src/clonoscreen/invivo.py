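"""Xenograft growth analysis: caliper volumes, group curves, comparisons.

Tumor volume from two-axis caliper measurements uses the modified-ellipsoid
formula V = (pi/6) * L * W**2 (L = length >= W = width, mm). Group curves
are summarized as mean +/- SEM per day; arms are compared with a two-way
(group x day) type-II ANOVA on volumes plus pairwise Welch t-tests at the
endpoint. Volumes past the 1000 mm^3 humane endpoint are flagged, never
dropped.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .stats import anova_twoway, ttest_two_tailed

__all__ = ["tumor_volume", "growth_summary", "HUMANE_ENDPOINT_MM3"]

HUMANE_ENDPOINT_MM3 = 1000.0


def tumor_volume(length_mm: float, width_mm: float,
                 literal_formula: bool = False) -> float:
    """Volume (mm^3) from caliper length and width.

    Default: V = (pi/6) * L * W**2, the standard modified-ellipsoid formula.
    ``literal_formula=True`` instead evaluates L * W**2 / (pi/6), an
    alternative convention seen in print that differs by a factor of
    (6/pi)^2; both are offered so reports can emit either. If width exceeds
    length the two are swapped with a warning.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError("caliper measurements must be nonnegative")
    if width_mm > length_mm:
        warnings.warn("width > length; swapping axes")
        length_mm, width_mm = width_mm, length_mm
    if literal_formula:
        return length_mm * width_mm ** 2 / (np.pi / 6.0)
    return (np.pi / 6.0) * length_mm * width_mm ** 2


def growth_summary(trajectories: pd.DataFrame,
                   volume_col: str = "volume_mm3") -> dict:
    """Per-group growth curves and statistical comparisons.

    Expects columns ``mouse_id, group, day`` and a volume column (computed
    from caliper data upstream if absent but ``length_mm``/``width_mm`` are
    present). Returns a dict with:

    ``curves``    mean/SEM/n per (group, day), available-case on missing days
    ``endpoint``  per-group summary at the last common day, with a flag for
                  volumes past the humane endpoint
    ``pairwise``  endpoint Welch t-tests for every group pair
    ``anova``     two-way (group x day) type-II ANOVA table
    ``unbalanced`` True when groups do not share all measurement days
    """
    df = trajectories.copy()
    if volume_col not in df.columns:
        if {"length_mm", "width_mm"}.issubset(df.columns):
            df[volume_col] = [tumor_volume(l, w) for l, w in
                              zip(df["length_mm"], df["width_mm"])]
        else:
            raise ValueError("no volume column and no caliper columns")
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if (df.groupby("group")["mouse_id"].nunique() < 2).any():
        raise ValueError("need >= 2 mice per group")

    curves = df.groupby(["group", "day"])[volume_col].agg(
        n="size", mean="mean",
        sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
    ).reset_index()

    days_per_group = df.groupby("group")["day"].agg(lambda s: frozenset(s))
    unbalanced = len(set(days_per_group)) > 1
    if unbalanced:
        warnings.warn("groups do not share all days; "
                      "curves use available cases")
    common = frozenset.intersection(*days_per_group)
    end_day = max(common) if common else df["day"].max()

    end = df[df["day"] == end_day]
    endpoint = end.groupby("group")[volume_col].agg(
        n="size", mean="mean",
        sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        past_humane_endpoint=lambda v: bool((v > HUMANE_ENDPOINT_MM3).any()),
    ).reset_index()
    endpoint["day"] = end_day

    pw = []
    for ga, gb in itertools.combinations(sorted(groups), 2):
        a = end[end["group"] == ga][volume_col].to_numpy()
        b = end[end["group"] == gb][volume_col].to_numpy()
        t, p = ttest_two_tailed(a, b)
        pw.append({"group_a": ga, "group_b": gb, "t": t, "p": p,
                   "significant": p < 0.05})
    pairwise = pd.DataFrame(pw)

    anova = anova_twoway(df, volume_col, "group", "day")
    return {"curves": curves, "endpoint": endpoint, "pairwise": pairwise,
            "anova": anova, "unbalanced": unbalanced}
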