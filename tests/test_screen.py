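"""SRF statistic, detectability, hit calling, ranking."""

import numpy as np
import pandas as pd
import pytest

from clonoscreen import (ScreenGenConfig, SrfScreen, assess_detectability,
                         compute_srf, hit_fraction, normalize_counts,
                         rank_screen, simulate_screen)
from conftest import make_well_table


def brute_force_srf(table: pd.DataFrame, conc: float) -> float:
    """Oracle: SRF from raw condition means by direct arithmetic."""
    def mean_of(kind):
        vals = []
        for _, r in table.iterrows():
            has_drug = np.isfinite(r["concentration"])
            ir = r["radiation_dose"] > 0
            k = ("combo" if has_drug and ir else "drug" if has_drug
                 else "ir" if ir else "control")
            if k == kind and (not has_drug or r["concentration"] == conc):
                vals.append(r["colony_count"])
        return sum(vals) / len(vals)

    ncn_2gy = mean_of("ir") / mean_of("control")
    ncn_drug = mean_of("drug") / mean_of("control")
    ncn_combo = mean_of("combo") / mean_of("control")
    return ncn_2gy * ncn_drug / ncn_combo


def test_ncn_from_replicate_means():
    """Means are taken before ratios: (48,50,52)/100 -> exactly 0.5."""
    table = make_well_table({
        ("control",): [100, 100, 100], ("ir",): [50, 50, 50],
        ("drug", 1e-9): [48, 50, 52], ("combo", 1e-9): [30, 30, 30]})
    ncn = normalize_counts(table)
    assert ncn.loc[0, "ncn_2gy"] == 0.5
    assert ncn.loc[0, "ncn_drug"] == 0.5
    assert ncn.loc[0, "n_drug"] == 3


def test_condition_equal_to_control_normalizes_to_one():
    table = make_well_table({
        ("control",): [40, 40], ("ir",): [40, 40],
        ("drug", 1e-9): [40, 40], ("combo", 1e-9): [40, 40]})
    ncn = normalize_counts(table)
    assert ncn.loc[0, ["ncn_2gy", "ncn_drug", "ncn_combo"]].tolist() \
        == [1.0, 1.0, 1.0]


@pytest.mark.parametrize("ncn2, ncnd, ncnc, expected", [
    (0.5, 0.8, 0.2, 2.0),              # hand evaluation
    (0.5, 0.8, 0.5 * 0.8, 1.0),        # multiplicative independence
    (1.0, 1.0, 1.0, 1.0),
])
def test_srf_formula(ncn2, ncnd, ncnc, expected):
    assert compute_srf(ncn2, ncnd, ncnc) == pytest.approx(expected)


def test_srf_undefined_when_combo_ncn_zero():
    assert np.isnan(compute_srf(0.5, 0.8, 0.0))


@pytest.mark.parametrize("mean_drug, mean_combo, detectable", [
    (0.0, 0.0, False),     # full kill
    (40.0, 10.0, True),    # both comfortably above floor
    (2.9, 10.0, False),    # drug arm below floor
    (40.0, 2.9, False),    # combo arm below floor
    (3.0, 3.0, True),      # floor is inclusive
    (np.nan, 10.0, False),
])
def test_detectability_rule(mean_drug, mean_combo, detectable):
    assert assess_detectability(mean_drug, mean_combo) is detectable


def test_hit_fraction_counts_over_detectable_entries():
    srf = np.array([2.0, 1.6, 1.4, 1.0, 9.9, np.nan])
    det = np.array([True, True, True, True, False, False])
    assert hit_fraction(srf, det) == pytest.approx(50.0)
    assert hit_fraction(np.array([2.0, 1.5]), np.array([True, True])) == 100.0
    assert np.isnan(hit_fraction(srf, np.zeros(6, dtype=bool)))


def test_normalization_requires_in_plate_control():
    table = make_well_table({("ir",): [50], ("drug", 1e-9): [40],
                             ("combo", 1e-9): [20]})
    with pytest.raises(ValueError, match="control"):
        normalize_counts(table)
    zero = make_well_table({("control",): [0, 0], ("ir",): [50],
                            ("drug", 1e-9): [40], ("combo", 1e-9): [20]})
    with pytest.raises(ValueError, match="zero"):
        normalize_counts(zero)


def test_plates_normalize_against_their_own_controls():
    p1 = make_well_table({("control",): [100], ("ir",): [50],
                          ("drug", 1e-9): [80], ("combo", 1e-9): [40]},
                         plate_id="P1")
    p2 = make_well_table({("control",): [200], ("ir",): [100],
                          ("drug", 1e-9): [160], ("combo", 1e-9): [80]},
                         plate_id="P2")
    ncn = normalize_counts(pd.concat([p1, p2], ignore_index=True))
    # same relative structure on both plates despite 2x absolute counts
    assert np.allclose(ncn["ncn_2gy"], 0.5)
    assert np.allclose(ncn["ncn_drug"], 0.8)


def _random_table(rng) -> pd.DataFrame:
    return make_well_table({
        ("control",): rng.integers(20, 120, 3).tolist(),
        ("ir",): rng.integers(10, 80, 3).tolist(),
        ("drug", 1e-9): rng.integers(10, 100, 3).tolist(),
        ("combo", 1e-9): rng.integers(5, 60, 3).tolist()})


def test_srf_matches_brute_force_oracle_on_random_tables():
    rng = np.random.default_rng(17)
    for _ in range(20):
        table = _random_table(rng)
        ncn = normalize_counts(table)
        srf = compute_srf(ncn.loc[0, "ncn_2gy"], ncn.loc[0, "ncn_drug"],
                          ncn.loc[0, "ncn_combo"])
        assert srf == pytest.approx(brute_force_srf(table, 1e-9), rel=1e-12)


def test_srf_invariant_to_rescaling_all_counts():
    rng = np.random.default_rng(23)
    table = _random_table(rng)
    scaled = table.assign(colony_count=table["colony_count"] * 7)

    def srf_of(t):
        ncn = normalize_counts(t)
        return compute_srf(ncn.loc[0, "ncn_2gy"], ncn.loc[0, "ncn_drug"],
                           ncn.loc[0, "ncn_combo"])

    assert srf_of(scaled) == pytest.approx(srf_of(table), rel=1e-12)


def test_srf_depends_inversely_on_the_control_mean():
    """SRF reduces to m_IR * m_drug / (m_combo * m_control): the control
    mean enters once and does not cancel, so doubling only the control
    counts exactly halves SRF (while doubling every count leaves it
    unchanged). Verified against the brute-force oracle."""
    rng = np.random.default_rng(29)
    table = _random_table(rng)
    is_ctrl = table["concentration"].isna() & (table["radiation_dose"] == 0)
    doubled = table.copy()
    doubled.loc[is_ctrl, "colony_count"] *= 2

    base = brute_force_srf(table, 1e-9)
    assert brute_force_srf(doubled, 1e-9) == pytest.approx(base / 2,
                                                           rel=1e-12)
    ncn = normalize_counts(doubled)
    assert compute_srf(ncn.loc[0, "ncn_2gy"], ncn.loc[0, "ncn_drug"],
                       ncn.loc[0, "ncn_combo"]) == pytest.approx(
        base / 2, rel=1e-12)


def test_ranking_orders_by_hit_fraction_then_srf():
    prof = pd.DataFrame({
        "drug_id": ["a", "a", "b", "b", "c", "c"],
        "concentration": [1e-9, 1e-10] * 3,
        "srf": [2.0, 1.0, 2.0, 1.9, np.nan, np.nan],
        "detectable": [True, True, True, True, False, False],
        "hit_fraction": [50.0, 50.0, 100.0, 100.0, np.nan, np.nan]})
    ranking, heat = rank_screen(prof)
    assert ranking["drug_id"].tolist() == ["b", "a", "c"]
    assert heat.index.tolist() == ["b", "a", "c"]
    assert heat.columns.tolist() == [1e-9, 1e-10]  # high conc first
    assert np.isnan(heat.loc["c"]).all()           # undetectable marked

    shuffled = prof.sample(frac=1.0, random_state=1).reset_index(drop=True)
    ranking2, _ = rank_screen(shuffled)
    assert ranking2["drug_id"].tolist() == ranking["drug_id"].tolist()


def test_single_drug_ranks_first():
    prof = pd.DataFrame({"drug_id": ["only"], "concentration": [1e-9],
                         "srf": [1.8], "detectable": [True],
                         "hit_fraction": [100.0]})
    ranking, _ = rank_screen(prof)
    assert ranking.loc[0, "rank"] == 1


def test_independent_drug_gives_srf_centered_at_one():
    """Across 200 simulated plates with f=1, mean detectable SRF ~ 1."""
    vals = []
    for seed in range(200):
        records, _ = simulate_screen(ScreenGenConfig(seed=seed))
        prof = SrfScreen().fit(records).profiles_
        vals.extend(prof.loc[prof["detectable"], "srf"].tolist())
    assert abs(np.mean(vals) - 1.0) < 0.05


def test_strong_sensitizer_yields_full_hit_fraction_in_most_seeds():
    """f=2 at moderate counting noise: hit fraction 100% in >= 95% of seeds.

    400 cells/well keeps the Poisson noise on condition means moderate; at
    the screen's 50 cells/well the single detectable concentration of a
    near-fully-cytotoxic compound is recovered by majority vote instead.
    """
    full = 0
    for seed in range(50):
        cfg = ScreenGenConfig(seed=seed, cells_seeded_per_well=400,
                              sensitization_factor=2.0)
        records, _ = simulate_screen(cfg)
        hf = SrfScreen().fit(records).hit_fractions_.iloc[0]
        full += hf == 100.0
    assert full / 50 >= 0.95


def test_bootstrap_interval_brackets_point_estimate():
    records, _ = simulate_screen(ScreenGenConfig(seed=4))
    model = SrfScreen(n_bootstrap=200, random_state=0).fit(records)
    det = model.profiles_[model.profiles_["detectable"]]
    assert ((det["srf_ci_low"] <= det["srf"])
            & (det["srf"] <= det["srf_ci_high"])).all()
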