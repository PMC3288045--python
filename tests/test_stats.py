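"""Normalization, paired t-tests and the interaction index."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from g1screen import (
    SimulationConfig,
    interaction_index,
    normalize_relative,
    paired_t,
    simulate_viability_arms,
    survival_curves,
)
from g1screen.config import ViabilityModel
from g1screen.errors import G1ScreenError
from g1screen.stats import average_technical, benjamini_hochberg, \
    interaction_from_observations


def test_normalize_relative_examples():
    assert normalize_relative([30.0], [60.0, 60.0])[0] == pytest.approx(0.5)
    vals = np.array([10.0, 12.0, 8.0])
    assert normalize_relative(vals, vals).mean() == pytest.approx(1.0)
    with pytest.raises(G1ScreenError):
        normalize_relative([1.0], [0.0, 0.0])


def test_paired_t_identical_and_worked_example():
    assert paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).t == 0.0
    assert paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).p == 1.0
    # differences (1,2,3): t = 2/(1/sqrt(3)) = 3.464, df = 2, p ~ 0.0742
    res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
    assert res.t == pytest.approx(2.0 * math.sqrt(3), rel=1e-12)
    assert res.df == 2
    assert res.p == pytest.approx(0.0742, abs=0.0005)


def test_paired_t_zero_variance_nonzero_difference():
    res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
    assert res.p == 0.0 and res.t == math.inf
    with pytest.raises(G1ScreenError):
        paired_t([1.0, 2.0], [1.0])


def test_paired_t_matches_sign_flip_enumeration():
    """Exact sign-flip permutation p on n <= 10 brackets the t-test p for
    symmetric null data (they agree within enumeration granularity)."""
    rng = np.random.default_rng(2)
    a = rng.normal(10, 1, 8)
    b = rng.normal(10, 1, 8)
    d = a - b
    t_obs = abs(paired_t(a, b).t)
    count = 0
    total = 0
    for signs in itertools.product([1, -1], repeat=len(d)):
        flipped = d * np.array(signs)
        m = flipped.mean()
        s = flipped.std(ddof=1)
        t = abs(m / (s / math.sqrt(len(d)))) if s > 0 else math.inf
        count += t >= t_obs - 1e-12
        total += 1
    perm_p = count / total
    assert paired_t(a, b).p == pytest.approx(perm_p, abs=0.06)


def test_paired_t_type_one_error_calibrated():
    """10^4 null trials with n=3 biological replicates: rejection rate at
    alpha=0.05 within Monte-Carlo error of 5%."""
    rng = np.random.default_rng(7)
    n_trials = 10_000
    a = rng.normal(0, 1, size=(n_trials, 3))
    b = rng.normal(0, 1, size=(n_trials, 3))
    rejections = sum(paired_t(a[i], b[i]).p < 0.05 for i in range(n_trials))
    rate = rejections / n_trials
    assert abs(rate - 0.05) < 3.0 * math.sqrt(0.05 * 0.95 / n_trials)


def test_interaction_index_worked_examples():
    # multiplicative null
    res = interaction_index(100, 50, 40, 20)
    assert res.index == pytest.approx(0.0, abs=1e-12)
    assert res.classification == "none"
    # stronger combined loss -> +0.1 -> synergy for a viability readout
    res = interaction_index(100, 50, 40, 10)
    assert res.index == pytest.approx(0.1)
    assert res.classification == "synergistic"
    # weaker combined loss -> -0.1 -> antagonism
    res = interaction_index(100, 50, 40, 30)
    assert res.index == pytest.approx(-0.1)
    assert res.classification == "antagonistic"


def test_interaction_direction_flips_classification():
    """For a readout that IR increases (e.g. p21 positivity), a positive
    index means the knockdown blunts the IR response: antagonism."""
    res = interaction_index(10, 8, 30, 12, direction="IR-increases-readout")
    assert res.index > 0
    assert res.classification == "antagonistic"


@given(st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.1, 100),
       st.floats(0.05, 20))
def test_multiplicative_null_identity(cc, rc, c_ir, scale):
    """index(Cc, Rc, C_IR, Rc*C_IR/Cc) = 0 exactly, for any positive inputs."""
    r_ir = rc * c_ir / cc
    res = interaction_index(cc, rc, c_ir, r_ir)
    tol = 1e-12 * max(1.0, abs(res.expected))
    assert abs(res.index) <= tol
    scaled = interaction_index(cc * scale, rc * scale, c_ir * scale, r_ir * scale)
    assert abs(scaled.index) <= tol


@given(st.floats(0.5, 2.0))
def test_interaction_rescaling_invariance(scale):
    base = interaction_index(100, 70, 40, 20)
    scaled = interaction_index(100 * scale, 70 * scale, 40 * scale, 20 * scale)
    assert scaled.index == pytest.approx(base.index, rel=1e-9)


def test_interaction_errors():
    with pytest.raises(G1ScreenError):
        interaction_index(0.0, 1, 1, 1)
    with pytest.raises(G1ScreenError):
        interaction_index(1.0, -1, 1, 1)
    with pytest.raises(G1ScreenError):
        interaction_index(1, 1, 1, 1, direction="sideways")


def test_average_technical_collapses_to_biological():
    obs = pd.DataFrame({
        "target": "t", "co_kd": "NT", "dose_gy": 0.0, "assay": "viability",
        "bio_rep": [1, 1, 2, 2], "tech_rep": [1, 2, 1, 2],
        "value": [1.0, 3.0, 5.0, 7.0]})
    bio = average_technical(obs)
    assert len(bio) == 2
    assert sorted(bio["value"]) == [2.0, 6.0]


def test_survival_curves_identity_and_synergy_arms():
    cfg = SimulationConfig(seed=15, viability=ViabilityModel.synergy(0.5))
    lum = simulate_viability_arms(cfg, n_bio=6)
    dr, inter = survival_curves(lum)
    # every arm is exactly 1 at its own dose-0 reference
    zero = dr[dr["dose_gy"] == 0.0]
    assert np.allclose(zero["surviving_fraction"], 1.0)
    # closed form: R_IR = 0.5 * expected, so index = 0.5 * expected
    null = ViabilityModel.multiplicative_null().survival
    for co in ("NT", "coKD"):
        for dose, idx in ((2.0, 1), (5.0, 2)):
            expected = (null["target/" + co][0]) * null["mock/" + co][idx]
            row = inter[(inter["co_kd"] == co) & (inter["dose_gy"] == dose)]
            assert row["index"].iloc[0] == pytest.approx(0.5 * expected, abs=0.04)
            assert row["classification"].iloc[0] == "synergistic"


def test_survival_curves_multiplicative_null_indices_near_zero():
    cfg = SimulationConfig(seed=16, viability=ViabilityModel.multiplicative_null())
    lum = simulate_viability_arms(cfg, n_bio=6)
    _, inter = survival_curves(lum)
    assert np.allclose(inter["index"], 0.0, atol=0.05)


def test_cokd_only_sensitization_detected():
    """A target sensitizing only under co-knockdown: index ~0 in the NT
    background, positive in the co-knockdown background."""
    surv = {
        "mock/NT": (1.0, 0.80, 0.55),
        "target/NT": (0.95, 0.95 * 0.80, 0.95 * 0.55),       # multiplicative
        "mock/coKD": (0.95, 0.78, 0.50),
        "target/coKD": (0.90, 0.30, 0.10),                   # synergy
    }
    cfg = SimulationConfig(seed=17, viability=ViabilityModel(survival=surv))
    lum = simulate_viability_arms(cfg, n_bio=6)
    _, inter = survival_curves(lum)
    nt = inter[inter["co_kd"] == "NT"]
    ck = inter[inter["co_kd"] == "coKD"]
    assert np.allclose(nt["index"], 0.0, atol=0.05)
    assert (ck["index"] > 0.1).all()
    assert (ck["classification"] == "synergistic").all()


def test_missing_dose_zero_reference_raises():
    obs = pd.DataFrame({
        "target": ["mock", "t"], "co_kd": "NT", "dose_gy": [2.0, 2.0],
        "bio_rep": 1, "tech_rep": 1, "value": [1.0, 0.5], "assay": "viability"})
    with pytest.raises(G1ScreenError):
        survival_curves(obs)


def test_interaction_from_observations_matches_direct_call():
    obs = pd.DataFrame({
        "target": ["mock"] * 2 + ["t"] * 2 + ["mock"] * 2 + ["t"] * 2,
        "co_kd": "NT",
        "dose_gy": [0.0, 0.0, 0.0, 0.0, 5.0, 5.0, 5.0, 5.0],
        "bio_rep": [1, 2] * 4, "tech_rep": 1,
        "value": [100, 100, 50, 50, 40, 40, 10, 10], "assay": "viability"})
    res = interaction_from_observations(obs, target="t", dose_gy=5.0)
    assert res.index == pytest.approx(0.1)


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.8, 0.04])
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
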