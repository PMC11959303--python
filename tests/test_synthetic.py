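"""Generator correctness: analytic means, determinism, ground-truth echo."""

import numpy as np
import pandas as pd
import pytest

from clonoscreen import (GroundTruth, ScreenGenConfig, expected_srf,
                         simulate_cck8, simulate_flow_apoptosis,
                         simulate_flow_cellcycle, simulate_growth,
                         simulate_screen)


@pytest.mark.parametrize("bad", [
    dict(concentration_ladder=(1e-9, 1e-8)),          # increasing
    dict(concentration_ladder=()),                     # empty
    dict(concentration_ladder=(1e-9, -1e-10)),         # negative
    dict(plating_efficiency=0.0),
    dict(plating_efficiency=1.3),
    dict(lq_alpha=-0.1),
    dict(sensitization_factor=-1.0),
    dict(sensitization_factor=(1.0, 2.0)),             # wrong length
    dict(replicates=0),
])
def test_screen_config_rejects_invalid(bad):
    with pytest.raises(ValueError):
        ScreenGenConfig(**bad)


def test_control_mean_is_cells_times_pe():
    """50 cells at PE 0.8 without treatment average 40 colonies."""
    cfg = ScreenGenConfig(plating_efficiency=0.8, replicates=20000, seed=3)
    records, _ = simulate_screen(cfg)
    ctrl = records[(records["radiation_dose"] == 0)
                   & (records["concentration"].isna())]["colony_count"]
    se = np.sqrt(40.0 / len(ctrl))
    assert abs(ctrl.mean() - 40.0) < 3 * se


def test_condition_means_match_analytic_poisson_means():
    """Empirical means of every condition converge to the model means."""
    cfg = ScreenGenConfig(replicates=10000, seed=5,
                          sensitization_factor=1.5)
    records, _ = simulate_screen(cfg)
    base = cfg.cells_seeded_per_well * cfg.plating_efficiency
    s_ir = cfg.ir_survival()

    def check(mask, mean):
        obs = records[mask]["colony_count"]
        se = max(np.sqrt(mean / len(obs)), 1e-6)
        assert abs(obs.mean() - mean) < max(3 * se, 1e-3)

    drugless = records["concentration"].isna()
    check(drugless & (records["radiation_dose"] == 0), base)
    check(drugless & (records["radiation_dose"] > 0), base * s_ir)
    for x in cfg.concentration_ladder:
        sd = cfg.drug_survival(x)
        at_x = records["concentration"] == x
        check(at_x & (records["radiation_dose"] == 0), base * sd)
        check(at_x & (records["radiation_dose"] > 0),
              base * sd * s_ir ** 1.5)


def test_expected_srf_is_one_under_independence():
    cfg = ScreenGenConfig(sensitization_factor=1.0)
    assert np.allclose(expected_srf(cfg), 1.0)


def test_expected_srf_exceeds_hit_threshold_under_sensitization():
    cfg = ScreenGenConfig(sensitization_factor=2.0)
    assert np.all(expected_srf(cfg) > 1.5)


def test_overdispersion_switch_inflates_variance():
    lean = simulate_screen(ScreenGenConfig(replicates=5000, seed=1))[0]
    fat = simulate_screen(ScreenGenConfig(replicates=5000, seed=1,
                                          overdispersion=2.0))[0]
    ctrl = lambda df: df[(df["radiation_dose"] == 0)
                         & (df["concentration"].isna())]["colony_count"]
    assert ctrl(fat).var() > 2 * ctrl(lean).var()


@pytest.mark.parametrize("maker", [
    lambda s: simulate_screen(ScreenGenConfig(seed=s))[0],
    lambda s: simulate_cck8(1e-9, 1.0, [1e-10, 1e-9, 1e-8], 0.05, 3, s)[0],
    lambda s: simulate_flow_apoptosis((0.4, 0.3, 0.2, 0.1), 500, s)[0],
    lambda s: simulate_flow_cellcycle((0.5, 0.2, 0.3), 500, 0.04, s)[0],
    lambda s: simulate_growth([(1.0, 3), (0.5, 3)], 100, 0.15,
                              [0, 3, 6], 0.1, s)[0],
])
def test_generators_are_bit_reproducible(maker):
    pd.testing.assert_frame_equal(maker(42), maker(42))


def test_ground_truth_round_trips_through_yaml(default_screen):
    _, truth = default_screen
    again = GroundTruth.from_yaml(truth.to_yaml())
    assert again.assay == truth.assay
    assert again.params == truth.params


# ---- CCK-8 ----------------------------------------------------------------

def test_cck8_noiseless_midpoint_is_half():
    table, _ = simulate_cck8(1e-9, 1.5, [1e-9], 0.0, 2, 0)
    assert np.allclose(table["viability"], 0.5)


def test_cck8_steep_hill_approaches_step_function():
    doses = [0.5e-9, 2e-9]
    table, _ = simulate_cck8(1e-9, 200.0, doses, 0.0, 1, 0)
    v = table.sort_values("dose")["viability"].to_numpy()
    assert v[0] > 0.999 and v[1] < 0.001


def test_cck8_rejects_bad_inputs():
    with pytest.raises(ValueError):
        simulate_cck8(1e-9, 1.0, [0.0, 1e-9], 0.0, 1, 0)
    with pytest.raises(ValueError):
        simulate_cck8(1e-9, 1.0, [1e-9], -0.1, 1, 0)


# ---- flow -----------------------------------------------------------------

def test_apoptosis_all_mass_in_viable_cluster():
    events, _ = simulate_flow_apoptosis((1.0, 0, 0, 0), 800, 2)
    assert (events["population"] == "viable").all()
    # viable cluster is low in both channels
    assert events["annexin"].median() < 100
    assert events["pi"].median() < 100


def test_apoptosis_empty_table_is_valid():
    events, truth = simulate_flow_apoptosis((0.25, 0.25, 0.25, 0.25), 0, 2)
    assert len(events) == 0
    assert truth.params["n_events"] == 0


def test_apoptosis_rejects_unnormalized_fractions():
    with pytest.raises(ValueError):
        simulate_flow_apoptosis((0.5, 0.5, 0.5, 0.5), 10, 0)


def test_cellcycle_g2_peak_at_twice_g1():
    events, _ = simulate_flow_cellcycle((0.5, 0.0, 0.5), 4000, 0.0, 9,
                                        g1_mean=80.0)
    vals = np.sort(events["dna_content"].unique())
    assert np.allclose(vals, [80.0, 160.0])


def test_cellcycle_pure_g1_is_single_gaussian():
    events, _ = simulate_flow_cellcycle((1.0, 0, 0), 3000, 0.04, 4)
    x = events["dna_content"]
    assert abs(x.mean() - 100.0) < 1.0
    assert abs(x.std() - 4.0) < 0.5


# ---- growth ---------------------------------------------------------------

def test_growth_noiseless_follows_exponential_closed_form():
    df, _ = simulate_growth([(1.0, 2)], 100.0, 0.2, [0, 5, 10], 0.0, 0)
    one = df[df["mouse_id"] == "m001"].sort_values("day")
    assert np.allclose(one["volume_mm3"], 100.0 * np.exp(0.2 * one["day"]))


def test_growth_zero_effect_is_flat_at_v0():
    df, _ = simulate_growth([(0.0, 2)], 120.0, 0.2, [0, 3, 6], 0.0, 0)
    assert np.allclose(df["volume_mm3"], 120.0)


def test_growth_calipers_reproduce_volume_and_aspect():
    df, _ = simulate_growth([(1.0, 3)], 100.0, 0.15, [0, 3], 0.2, 8)
    recon = (np.pi / 6.0) * df["length_mm"] * df["width_mm"] ** 2
    assert np.allclose(recon, df["volume_mm3"])
    assert (df["length_mm"] >= df["width_mm"]).all()
    assert np.allclose(df["length_mm"] / df["width_mm"], 1.25)


def test_growth_four_arm_design_uses_standard_names():
    df, _ = simulate_growth([(1.0, 6), (0.8, 6), (0.6, 6), (0.3, 6)],
                            100.0, 0.15, [0, 3], 0.1, 0)
    assert set(df["group"]) == {"PBS", "drug", "IR", "drug+IR"}
    assert (df.groupby("group")["mouse_id"].nunique() == 6).all()


def test_growth_rejects_nonpositive_v0():
    with pytest.raises(ValueError):
        simulate_growth([(1.0, 2)], 0.0, 0.1, [0], 0.0, 0)
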