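"""Gate derivation and responder-fraction counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import gaussian_kde

from g1screen import (
    GateSpec,
    MissingChannelError,
    NoSeparationError,
    derive_gate,
    g1_fraction,
    pos_fraction,
    simulate_reporter_well,
)
from g1screen.config import GateConfig
from g1screen.errors import G1ScreenError
from g1screen.gating import summarize_plate


def _lognormal(rng, median, sigma, n):
    return rng.lognormal(np.log(median), sigma, size=n)


def test_equal_spread_gate_at_geometric_midpoint(rng):
    """Equal log-spreads force the density crossing to the log-midpoint."""
    neg = _lognormal(rng, 100.0, 0.1, 50000)
    pos = _lognormal(rng, 40.0, 0.1, 50000)
    gate = derive_gate(neg, pos, channel="ch_marker", direction="below")
    assert gate.threshold == pytest.approx(np.sqrt(100 * 40), rel=0.05)
    lo, hi = sorted((np.median(neg), np.median(pos)))
    assert lo < gate.threshold < hi


def test_identical_controls_raise_no_separation(rng):
    same = _lognormal(rng, 80.0, 0.15, 5000)
    with pytest.raises(NoSeparationError):
        derive_gate(same[:2500], same[2500:], channel="ch_marker",
                    direction="below")


def test_too_few_control_cells_raise(rng):
    neg = _lognormal(rng, 100.0, 0.1, 400)
    pos = _lognormal(rng, 40.0, 0.1, 400)
    with pytest.raises(G1ScreenError):
        derive_gate(neg, pos, channel="ch_marker", direction="below")


def test_unequal_spread_gate_matches_grid_scan_oracle(rng):
    """Crossing with unequal spreads equals a brute-force 0.1-AFU grid scan
    of the two kernel-density estimates between the medians."""
    neg = _lognormal(rng, 100.0, 0.1, 20000)
    pos = _lognormal(rng, 40.0, 0.3, 20000)
    params = GateConfig()
    gate = derive_gate(neg, pos, channel="ch_marker", direction="below",
                       params=params)

    # oracle: same pooled-bandwidth KDEs evaluated on a 0.1-AFU linear grid
    def subsample(v):
        v = np.sort(v)
        idx = np.linspace(0, len(v) - 1, params.max_kde_sample).round().astype(int)
        return np.log(v[idx])

    sn, sp = subsample(neg), subsample(pos)
    kn, kp = gaussian_kde(sn), gaussian_kde(sp)
    bw = 0.5 * (kn.factor * sn.std(ddof=1) + kp.factor * sp.std(ddof=1))
    kn.set_bandwidth(bw / sn.std(ddof=1))
    kp.set_bandwidth(bw / sp.std(ddof=1))
    grid = np.arange(np.median(pos), np.median(neg), 0.1)
    diff = kn(np.log(grid)) - kp(np.log(grid))
    oracle = grid[np.argmin(np.abs(diff))]
    assert gate.threshold == pytest.approx(oracle, abs=0.5)


def test_gate_provenance_recorded(rng):
    neg = _lognormal(rng, 100.0, 0.1, 2000)
    pos = _lognormal(rng, 40.0, 0.1, 2000)
    gate = derive_gate(neg, pos, channel="ch_marker", direction="below")
    assert gate.derivation["n_neg_cells"] == 2000
    assert gate.derivation["method"].startswith("kde-crossing")
    assert gate.derivation["neg_median"] == pytest.approx(100.0, rel=0.05)


@given(scale=st.floats(min_value=0.1, max_value=50.0))
def test_gate_threshold_scales_with_common_intensity_factor(scale):
    """Scaling all intensities by a common factor scales the threshold and
    leaves responder fractions unchanged."""
    rng = np.random.default_rng(77)
    neg = _lognormal(rng, 100.0, 0.12, 4000)
    pos = _lognormal(rng, 40.0, 0.12, 4000)
    cells = _lognormal(rng, 70.0, 0.4, 2000)
    g1 = derive_gate(neg, pos, channel="ch_marker", direction="below")
    g2 = derive_gate(neg * scale, pos * scale, channel="ch_marker",
                     direction="below")
    assert g2.threshold == pytest.approx(g1.threshold * scale, rel=0.02)
    f1 = pos_fraction(cells, g1, metric="POS").pos_fraction
    gate_scaled = GateSpec("ch_marker", g1.threshold * scale, "below")
    f2 = pos_fraction(cells * scale, gate_scaled, metric="POS").pos_fraction
    assert f1 == pytest.approx(f2)


def test_pos_fraction_counting_and_flags():
    gate = GateSpec(channel="ch_marker", threshold=50.0, direction="below")
    cells = np.concatenate([np.full(300, 10.0), np.full(1700, 100.0)])
    s = pos_fraction(cells, gate, metric="POS")
    assert s.pos_fraction == pytest.approx(15.0)
    assert not s.low_cell_count
    all_above = pos_fraction(np.full(2000, 100.0), gate)
    assert all_above.pos_fraction == 0.0
    flagged = pos_fraction(np.full(1200, 10.0), gate)
    assert flagged.low_cell_count and flagged.pos_fraction == 100.0
    with pytest.raises(G1ScreenError):
        pos_fraction(np.array([]), gate)


@given(threshold=st.floats(min_value=20.0, max_value=200.0))
def test_pos_fraction_directions_partition_every_well(threshold):
    rng = np.random.default_rng(5)
    cells = rng.lognormal(np.log(70.0), 0.5, 1000)
    below = pos_fraction(cells, GateSpec("ch_marker", threshold, "below"))
    above = pos_fraction(cells, GateSpec("ch_marker", threshold, "above"))
    assert below.pos_fraction + above.pos_fraction == pytest.approx(100.0)


def test_pos_fraction_recovers_planted_fraction_at_20k_cells():
    """3-sigma-separated components, 20000 cells: planted 30% within 1pp."""
    rng = np.random.default_rng(31)
    n, p = 20000, 0.30
    k = rng.binomial(n, p)
    cells = np.concatenate([
        rng.lognormal(np.log(40.0), np.log(2.5) / 6, k),
        rng.lognormal(np.log(100.0), np.log(2.5) / 6, n - k)])
    neg = rng.lognormal(np.log(100.0), np.log(2.5) / 6, 20000)
    pos = rng.lognormal(np.log(40.0), np.log(2.5) / 6, 20000)
    gate = derive_gate(neg, pos, channel="ch_marker", direction="below")
    est = pos_fraction(cells, gate).pos_fraction
    assert est == pytest.approx(30.0, abs=1.0)


def test_g1_fraction_threshold_inclusive_and_dropped_cells():
    df = pd.DataFrame({
        "plate_id": "P", "well": "A01", "cell_id": [1, 2, 3],
        "ch_dna": 200.0, "ch_marker": np.nan,
        "ch_gfp_nuc": [50.0, 38.0, 10.0],
        "ch_gfp_cyto": [20.0, 20.0, 0.0],
    })
    s = g1_fraction(df, ratio_threshold=2.0)
    # ratio 2.5 counts, 1.9 does not, zero-cytoplasm cell dropped
    assert s.n_cells == 2
    assert s.n_dropped == 1
    assert s.pos_fraction == pytest.approx(50.0)


def test_g1_fraction_requires_reporter_channels():
    df = pd.DataFrame({"plate_id": "P", "well": "A01", "cell_id": [1],
                       "ch_dna": [200.0], "ch_marker": [50.0],
                       "ch_gfp_nuc": [np.nan], "ch_gfp_cyto": [np.nan]})
    with pytest.raises(MissingChannelError):
        g1_fraction(df)


def test_g1_fraction_recovers_planted_reporter_fraction():
    cells = simulate_reporter_well(2000, 0.55, seed=12)
    s = g1_fraction(cells, ratio_threshold=2.0)
    assert s.pos_fraction == pytest.approx(55.0, abs=1.5)


def test_summarize_plate_matches_per_well_counting(small_screen, small_analysis):
    pid = small_screen.plate_ids[0]
    cells = small_screen.cells_for_plate(pid)
    gate = small_analysis.gates[pid]
    table = summarize_plate(cells, gate)
    one_well = table["well"].iloc[5]
    direct = pos_fraction(cells[cells["well"] == one_well], gate)
    row = table[table["well"] == one_well].iloc[0]
    assert row["pos_fraction"] == pytest.approx(direct.pos_fraction)
    assert row["n_cells"] == direct.n_cells


def test_estimated_fractions_unbiased_across_wells(small_screen, small_analysis):
    """Across >= 100 simulated wells the gated estimates are unbiased within
    binomial Monte-Carlo error."""
    merged = small_analysis.well_summaries.merge(
        small_screen.truth, on=["plate_id", "well"])
    errs = merged["pos_fraction"] - 100.0 * merged["true_fraction"]
    assert len(errs) >= 100
    # per-well binomial sd ~1pp at n=2500; mean error over N wells
    assert abs(errs.mean()) < 3.0 * 1.0 / np.sqrt(len(errs)) + 0.15
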