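"""Generator contracts: determinism, planted truth, convergence, viability
and profile structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from g1screen import (
    ConfigurationError,
    RunConfig,
    analyze_screen,
    SimulationConfig,
    simulate_profile_matrix,
    simulate_reporter_well,
    simulate_screen,
    simulate_viability_arms,
    simulate_well_level_screen,
)
from g1screen.config import ViabilityModel
from g1screen.simulate import DEFAULT_GROUPS
from g1screen.pipeline import analyze_well_level_screen
from g1screen.stats import survival_curves


def test_same_seed_bitwise_identical_different_seed_differs():
    cfg = SimulationConfig(seed=42, n_targets=20, cells_per_well=400)
    a = simulate_screen(cfg)
    b = simulate_screen(cfg)
    pid = a.plate_ids[0]
    pd.testing.assert_frame_equal(a.cells_for_plate(pid), b.cells_for_plate(pid))
    pd.testing.assert_frame_equal(a.plate_map, b.plate_map)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    c = simulate_screen(SimulationConfig(seed=43, n_targets=20, cells_per_well=400))
    assert not a.cells_for_plate(pid)["ch_marker"].equals(
        c.cells_for_plate(pid)["ch_marker"])


def test_positive_control_truth_is_baseline():
    """Full suppression pulls p21-siRNA wells back to the unirradiated baseline."""
    cfg = SimulationConfig(seed=1, n_targets=20)
    sim = simulate_screen(cfg)
    truth = sim.truth
    pos_ir = truth[(truth["role"] == "pos") & (truth["treatment_gy"] > 0)]
    assert (pos_ir["true_fraction"] == cfg.baseline_responder_fraction).all()
    mock_ir = truth[(truth["role"] == "mock") & (truth["treatment_gy"] > 0)]
    assert (mock_ir["true_fraction"] == cfg.ir_responder_fraction).all()


def test_every_well_has_cells_and_both_runs_produced():
    cfg = SimulationConfig(seed=5, n_targets=30, cells_per_well=3.0)
    sim = simulate_screen(cfg)
    doses = set(sim.plate_map["treatment_gy"].unique())
    assert doses == {0.0, cfg.ir_dose_gy}
    for pid in sim.plate_ids:
        counts = sim.cells_for_plate(pid).groupby("well").size()
        layout_wells = set(sim.plate_map.loc[sim.plate_map["plate_id"] == pid, "well"])
        assert set(counts.index) == layout_wells
        assert (counts >= 1).all()


def test_empirical_fraction_converges_to_truth():
    """At 20k cells/well the gated estimate sits within 2pp of the truth table."""
    cfg = SimulationConfig(seed=9, n_targets=12, cells_per_well=20000.0)
    sim = simulate_screen(cfg)
    pid = sim.plate_ids[0]
    cells = sim.cells_for_plate(pid)
    truth = sim.truth[sim.truth["plate_id"] == pid].set_index("well")
    midpoint = np.sqrt(cfg.intensity.lo_median * cfg.intensity.hi_median)
    for well, grp in cells.groupby("well"):
        est = 100.0 * (grp["ch_marker"] < midpoint).mean()
        assert abs(est - 100.0 * truth.loc[well, "true_fraction"]) < 2.0


def test_marginal_mixture_weights_sum_to_one():
    cfg = SimulationConfig(seed=3, n_targets=12, cells_per_well=5000.0)
    sim = simulate_screen(cfg)
    cells = sim.cells_for_plate(sim.plate_ids[0])
    midpoint = np.sqrt(cfg.intensity.lo_median * cfg.intensity.hi_median)
    lo = (cells["ch_marker"] < midpoint).mean()
    hi = (cells["ch_marker"] >= midpoint).mean()
    assert lo + hi == pytest.approx(1.0)
    assert 0 < lo < 1


def test_well_level_null_screen_tail_matches_normal_oracle():
    """Across >= 50 null screens the mean count of z < -1.5 targets matches
    779 * Phi(-1.5) within Monte-Carlo (binomial) error."""
    n_screens = 50
    expected = 779 * norm.cdf(-1.5)
    per_screen_sd = np.sqrt(779 * norm.cdf(-1.5) * (1 - norm.cdf(-1.5)))
    counts = []
    run_cfg = RunConfig(seed=0)
    for s in range(n_screens):
        cfg = SimulationConfig(seed=10_000 + s)
        screen = simulate_well_level_screen(cfg)
        table = analyze_well_level_screen(screen, run_cfg)
        counts.append(int((table["z_score"] < -1.5).sum()))
    mean_count = np.mean(counts)
    tol = 3.0 * per_screen_sd / np.sqrt(n_screens)
    assert abs(mean_count - expected) < tol


def test_well_level_path_consistent_with_per_cell_path():
    """The analytic well-level shortcut reproduces the per-cell + KDE route:
    same mock baseline and same library population spread, within sampling
    error."""
    cfg = SimulationConfig(seed=21, n_targets=100)
    sim = simulate_screen(cfg)
    analysis_cells = analyze_screen(sim, RunConfig(seed=21, simulation=cfg))
    fast = simulate_well_level_screen(SimulationConfig(seed=22, n_targets=100))
    mock_fast = fast["ir"]["mock_mean"]
    assert analysis_cells.baseline_mean == pytest.approx(mock_fast, abs=1.0)
    sd_cells = analysis_cells.table["mean_pos"].std(ddof=1)
    sd_fast = fast["ir"]["target_means"].std(ddof=1)
    assert sd_cells == pytest.approx(sd_fast, rel=0.35)


def test_viability_identity_arm_and_unknown_arm():
    cfg = SimulationConfig(seed=4, viability=ViabilityModel(survival={
        "mock/NT": (1.0, 1.0, 1.0), "target/NT": (1.0, 0.5, 0.25)}))
    lum = simulate_viability_arms(cfg, arms=["mock/NT", "target/NT"])
    assert (lum["value"] > 0).all()
    dr, _ = survival_curves(lum)
    mock = dr[(dr["target"] == "mock")]
    for dose in (2.0, 5.0):
        sf = mock.loc[mock["dose_gy"] == dose, "surviving_fraction"].iloc[0]
        assert sf == pytest.approx(1.0, abs=0.1)
    with pytest.raises(ConfigurationError):
        simulate_viability_arms(cfg, arms=["mock/banana"])


def test_viability_survival_ratios_match_config_in_expectation():
    cfg = SimulationConfig(seed=6)
    lum = simulate_viability_arms(cfg, n_bio=20, n_tech=3)
    dr, _ = survival_curves(lum)
    surv = cfg.viability.survival
    for (target, co), grp in dr.groupby(["target", "co_kd"]):
        arm = f"{target}/{co}"
        s0, s2, s5 = surv[arm]
        got2 = grp.loc[grp["dose_gy"] == 2.0, "surviving_fraction"].iloc[0]
        got5 = grp.loc[grp["dose_gy"] == 5.0, "surviving_fraction"].iloc[0]
        assert got2 == pytest.approx(s2 / s0, rel=0.05)
        assert got5 == pytest.approx(s5 / s0, rel=0.05)


def test_reporter_well_has_planted_ratio_fraction():
    cells = simulate_reporter_well(20000, 0.55, seed=8)
    ratio = cells["ch_gfp_nuc"] / cells["ch_gfp_cyto"]
    assert 100.0 * (ratio >= 2.0).mean() == pytest.approx(55.0, abs=1.5)


def test_profile_matrix_zero_noise_and_errors():
    m = simulate_profile_matrix(DEFAULT_GROUPS, noise_sd=0.0, seed=0)
    assert list(m.index) == list(DEFAULT_GROUPS)
    # identical rows within a group at zero noise
    g1 = [t for t, g in DEFAULT_GROUPS.items() if g == "I"]
    assert np.allclose(m.loc[g1].std(axis=0), 0.0)
    # duplicated single-group rows: all pairwise distances zero
    mono = simulate_profile_matrix({"A": "I", "B": "I", "C": "I"},
                                   noise_sd=0.0, seed=0)
    assert np.allclose(mono.to_numpy() - mono.to_numpy()[0], 0.0)
    with pytest.raises(ConfigurationError):
        simulate_profile_matrix({"A": "I"}, noise_sd=0.0)
    with pytest.raises(ConfigurationError):
        simulate_profile_matrix({"A": "X", "B": "X"}, noise_sd=0.0)
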