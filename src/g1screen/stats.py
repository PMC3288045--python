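"""Phenotype statistics: normalization, paired t-tests and the
knockdown x treatment interaction index.

The interaction index follows the Bliss-style multiplicative expectation:
with Cc the untreated mock readout, Rc the untreated knockdown readout,
C_IR the irradiated mock readout and R_IR the irradiated knockdown readout,

    index = (Rc/Cc) * (C_IR/Cc) - (R_IR/Cc)

An interaction is synergistic when the treatment effect in the knockdown arm
exceeds that in the mock arm (in the assay's response direction) and
antagonistic in the opposite case; indices within a configurable tolerance
of zero are classified as no interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import G1ScreenError

#: assay response directions: what irradiation does to the raw readout
DIRECTIONS = ("IR-increases-readout", "IR-decreases-readout")


@dataclass
class TTestResult:
    t: float
    p: float
    df: int


@dataclass
class InteractionResult:
    rc_over_cc: float
    cir_over_cc: float
    rir_over_cc: float
    expected: float
    index: float
    classification: str   # synergistic | antagonistic | none
    direction: str


def normalize_relative(values, reference) -> np.ndarray:
    """Divide observations by the mean of their matched reference group."""
    ref = np.asarray(reference, dtype=float)
    ref_mean = ref.mean()
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise G1ScreenError("reference mean must be positive")
    return np.asarray(values, dtype=float) / ref_mean


def average_technical(obs: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates to one value per biological replicate.

    Expects the tidy observation dialect and collapses over ``tech_rep``;
    all tests downstream pair on biological replicates only so that degrees
    of freedom are not overstated.
    """
    keys = [c for c in ("target", "co_kd", "dose_gy", "assay", "bio_rep")
            if c in obs.columns]
    return obs.groupby(keys, as_index=False)["value"].mean()


def paired_t(values_a, values_b) -> TTestResult:
    """Student's paired t-test across biological replicates (two-sided).

    Zero variance of the paired differences is handled explicitly: identical
    vectors give t = 0, p = 1; a constant nonzero difference is reported as
    the limit t = +/-inf, p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise G1ScreenError("paired vectors must have equal length")
    if len(a) < 2:
        raise G1ScreenError("need >= 2 pairs")
    d = a - b
    df = len(d) - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return TTestResult(t=0.0, p=1.0, df=df)
        return TTestResult(t=math.copysign(math.inf, d.mean()), p=0.0, df=df)
    res = sps.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=df)


def interaction_index(cc: float, rc: float, c_ir: float, r_ir: float,
                      direction: str = "IR-decreases-readout",
                      tolerance: float = 0.02) -> InteractionResult:
    """Knockdown x treatment interaction index and its classification.

    All four readouts are on the raw assay scale; the index is invariant
    under a common positive rescaling.  ``direction`` states whether the
    treatment raises or lowers the readout in competent cells, which fixes
    the synergy/antagonism reading of the index sign.
    """
    if direction not in DIRECTIONS:
        raise G1ScreenError(f"direction must be one of {DIRECTIONS}")
    if cc <= 0:
        raise G1ScreenError("untreated mock readout Cc must be positive")
    for name, v in (("Rc", rc), ("C_IR", c_ir), ("R_IR", r_ir)):
        if v < 0:
            raise G1ScreenError(f"readout {name} must be non-negative")
    rc_cc = rc / cc
    cir_cc = c_ir / cc
    rir_cc = r_ir / cc
    expected = rc_cc * cir_cc
    index = expected - rir_cc
    if abs(index) <= tolerance:
        cls = "none"
    else:
        # index > 0 <=> relative treatment effect is larger in the knockdown
        # arm for a decreasing readout (synergy), and smaller for an
        # increasing readout (antagonism).
        if direction == "IR-decreases-readout":
            cls = "synergistic" if index > 0 else "antagonistic"
        else:
            cls = "antagonistic" if index > 0 else "synergistic"
    return InteractionResult(
        rc_over_cc=rc_cc, cir_over_cc=cir_cc, rir_over_cc=rir_cc,
        expected=expected, index=index, classification=cls, direction=direction,
    )


def interaction_from_observations(obs: pd.DataFrame, target: str,
                                  dose_gy: float, co_kd: str = "NT",
                                  mock_label: str = "mock",
                                  direction: str = "IR-decreases-readout",
                                  tolerance: float = 0.02) -> InteractionResult:
    """Interaction index for one target/dose within one co-knockdown background,
    from tidy observations (technical replicates averaged first)."""
    bio = average_technical(obs)
    sel = bio["co_kd"] == co_kd

    def mean_of(label: str, dose: float) -> float:
        vals = bio.loc[sel & (bio["target"] == label) & (bio["dose_gy"] == dose), "value"]
        if vals.empty:
            raise G1ScreenError(
                f"no observations for {label!r} at {dose} Gy in background {co_kd!r}")
        return float(vals.mean())

    return interaction_index(
        cc=mean_of(mock_label, 0.0), rc=mean_of(target, 0.0),
        c_ir=mean_of(mock_label, dose_gy), r_ir=mean_of(target, dose_gy),
        direction=direction, tolerance=tolerance,
    )


def survival_curves(obs: pd.DataFrame, mock_label: str = "mock",
                    tolerance: float = 0.02) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized dose-response table and per-background interaction indices.

    Each (target, co_kd) arm is normalized to its own untreated mean; the
    interaction index is then computed per irradiated dose within each
    co-knockdown background.  Returns ``(dose_response, interactions)``.
    """
    bio = average_technical(obs)
    doses = sorted(bio["dose_gy"].unique())
    if 0.0 not in doses:
        raise G1ScreenError("observations must include a 0 Gy reference")
    rows = []
    for (target, co), grp in bio.groupby(["target", "co_kd"], sort=True):
        ref = grp.loc[grp["dose_gy"] == 0.0, "value"]
        if ref.empty:
            raise G1ScreenError(f"arm ({target!r}, {co!r}) lacks a 0 Gy reference")
        for dose, sub in grp.groupby("dose_gy", sort=True):
            rel = normalize_relative(sub["value"], ref)
            rows.append((target, co, dose, float(rel.mean()),
                         float(np.std(rel, ddof=1)) if len(rel) > 1 else 0.0,
                         len(rel)))
    dose_response = pd.DataFrame(
        rows, columns=["target", "co_kd", "dose_gy", "surviving_fraction",
                       "sd", "n_bio"])
    irows = []
    targets = [t for t in bio["target"].unique() if t != mock_label]
    for co in sorted(bio["co_kd"].unique()):
        for target in targets:
            for dose in doses:
                if dose == 0.0:
                    continue
                res = interaction_from_observations(
                    obs, target=target, dose_gy=dose, co_kd=co,
                    mock_label=mock_label, tolerance=tolerance)
                irows.append((target, co, dose, res.expected, res.rir_over_cc,
                              res.index, res.classification))
    interactions = pd.DataFrame(
        irows, columns=["target", "co_kd", "dose_gy", "expected",
                        "observed", "index", "classification"])
    return dose_response, interactions


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default everywhere)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
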