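"""Single-cell gating: from per-cell intensities to per-well responder fractions.

Gates are anchored on in-plate control wells: the threshold is placed at the
crossing point of the kernel-density estimates of the pooled negative and
positive control log-intensity distributions (falling back to the midpoint of
the log-medians if no unique crossing lies between them).  Responder
percentages (POS metrics) are then simple threshold counts per well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .config import GateConfig
from .errors import MissingChannelError, NoSeparationError, G1ScreenError

DIRECTIONS = ("below", "above")


@dataclass
class GateSpec:
    """A derived intensity gate with its provenance."""

    channel: str
    threshold: float          # AFU for intensity gates, dimensionless for ratios
    direction: str            # responder "below" or "above" the threshold
    derivation: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise G1ScreenError(f"gate direction must be one of {DIRECTIONS}")
        if not np.isfinite(self.threshold) or self.threshold <= 0:
            raise G1ScreenError("gate threshold must be finite and positive")


@dataclass
class WellSummary:
    """Per-well responder percentage with cell count and QC flag."""

    plate_id: str
    well: str
    metric: str
    n_cells: int
    pos_fraction: float       # percentage in [0, 100]
    low_cell_count: bool
    n_dropped: int = 0        # cells unusable for the metric (e.g. zero cytoplasm)


def _intensities(cells, channel: str) -> np.ndarray:
    """Channel values as a float array from a DataFrame or array-like."""
    if isinstance(cells, pd.DataFrame):
        if channel not in cells.columns:
            raise MissingChannelError(f"channel {channel!r} missing from cell table")
        values = cells[channel].to_numpy(dtype=float)
    else:
        values = np.asarray(cells, dtype=float)
    if values.ndim != 1:
        raise G1ScreenError("cell intensities must be one-dimensional")
    if np.isnan(values).all():
        raise MissingChannelError(f"channel {channel!r} has no values")
    return values


def _even_subsample(values: np.ndarray, cap: int) -> np.ndarray:
    """Deterministic subsample: every k-th order statistic of the sorted data."""
    if len(values) <= cap:
        return np.sort(values)
    idx = np.linspace(0, len(values) - 1, cap).round().astype(int)
    return np.sort(values)[idx]


def derive_gate(neg_control_cells, pos_control_cells, channel: str,
                direction: str, params: GateConfig | None = None) -> GateSpec:
    """Place a responder gate between in-plate control distributions.

    The crossing of the two control KDEs on log intensity is independent of
    the mixing weights of a shared two-component mixture, so it recovers the
    component-density equality point even when both controls are mixtures.

    Raises :class:`NoSeparationError` when the control log-medians differ by
    less than ``params.min_log_separation``.
    """
    params = params or GateConfig()
    if direction not in DIRECTIONS:
        raise G1ScreenError(f"gate direction must be one of {DIRECTIONS}")
    neg = _intensities(neg_control_cells, channel)
    pos = _intensities(pos_control_cells, channel)
    neg = neg[np.isfinite(neg) & (neg > 0)]
    pos = pos[np.isfinite(pos) & (pos > 0)]
    if len(neg) < params.min_control_cells or len(pos) < params.min_control_cells:
        raise G1ScreenError(
            f"need >= {params.min_control_cells} cells per control group "
            f"(got {len(neg)} negative, {len(pos)} positive)")
    log_neg = np.log(neg)
    log_pos = np.log(pos)
    med_n = float(np.median(log_neg))
    med_p = float(np.median(log_pos))
    if abs(med_n - med_p) < params.min_log_separation:
        raise NoSeparationError(
            f"control log-medians separated by {abs(med_n - med_p):.4f} "
            f"< {params.min_log_separation}")
    sub_n = _even_subsample(log_neg, params.max_kde_sample)
    sub_p = _even_subsample(log_pos, params.max_kde_sample)
    kde_n = gaussian_kde(sub_n)
    kde_p = gaussian_kde(sub_p)
    # a common absolute bandwidth keeps the density crossing of two mixtures
    # of the same components at the component-equality point; per-sample
    # Scott bandwidths would smooth the broader control more and bias it
    bw = 0.5 * (kde_n.factor * sub_n.std(ddof=1) + kde_p.factor * sub_p.std(ddof=1))
    kde_n.set_bandwidth(bw / sub_n.std(ddof=1))
    kde_p.set_bandwidth(bw / sub_p.std(ddof=1))

    def crossings(lo: float, hi: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        grid = np.linspace(lo, hi, params.kde_grid)
        diff = kde_n(grid) - kde_p(grid)
        idx = np.flatnonzero(np.diff(np.sign(diff)) != 0)
        return grid, diff, idx

    # Prefer a crossing between the control medians (well-separated unimodal
    # controls); mixture-shaped controls sharing the same two components
    # cross at the component-density equality point, which can sit below
    # both mixture medians, so widen the search before falling back.
    lo, hi = sorted((med_n, med_p))
    grid, diff, idx = crossings(lo, hi)
    method = "kde-crossing"
    if len(idx) == 0:
        pooled = np.concatenate([log_neg, log_pos])
        q_lo, q_hi = np.quantile(pooled, [0.005, 0.995])
        grid, diff, idx = crossings(q_lo, q_hi)
        method = "kde-crossing-wide"
    if len(idx) >= 1:
        mid = 0.5 * (med_n + med_p)
        i = idx[np.argmin(np.abs(grid[idx] - mid))] if len(idx) > 1 else idx[0]
        # linear interpolation of the root between grid points
        x0, x1 = grid[i], grid[i + 1]
        y0, y1 = diff[i], diff[i + 1]
        log_thr = x0 - y0 * (x1 - x0) / (y1 - y0)
    else:
        log_thr = 0.5 * (med_n + med_p)
        method = "log-median-midpoint"
    return GateSpec(
        channel=channel,
        threshold=float(np.exp(log_thr)),
        direction=direction,
        derivation={
            "method": method,
            "n_neg_cells": int(len(neg)),
            "n_pos_cells": int(len(pos)),
            "neg_median": float(np.exp(med_n)),
            "pos_median": float(np.exp(med_p)),
        },
    )


def pos_fraction(cells, gate: GateSpec, min_cells: int = 1500,
                 metric: str = "POS", plate_id: str = "", well: str = "") -> WellSummary:
    """Responder percentage of one well under an intensity gate.

    Cells strictly below the threshold count as responders for a "below"
    gate; the complement (>= threshold) defines the non-responder side, so
    the two directions partition every well exactly.
    """
    values = _intensities(cells, gate.channel)
    values = values[np.isfinite(values)]
    n = len(values)
    if n == 0:
        raise G1ScreenError(f"well {well or '?'} has zero evaluable cells")
    if gate.direction == "below":
        k = int(np.count_nonzero(values < gate.threshold))
    else:
        k = int(np.count_nonzero(values >= gate.threshold))
    if isinstance(cells, pd.DataFrame):
        if not plate_id and "plate_id" in cells.columns:
            plate_id = str(cells["plate_id"].iloc[0])
        if not well and "well" in cells.columns:
            well = str(cells["well"].iloc[0])
    return WellSummary(
        plate_id=plate_id, well=well, metric=metric, n_cells=n,
        pos_fraction=100.0 * k / n, low_cell_count=n < min_cells,
    )


def g1_fraction(cells, ratio_threshold: float = 2.0, min_cells: int = 1500,
                direction: str = "above", metric: str = "POS-G1",
                plate_id: str = "", well: str = "") -> WellSummary:
    """Percentage of cells whose nuclear/cytoplasmic reporter ratio marks G1.

    With the default direction a cell counts as G1 when the ratio is >= the
    threshold (nuclear reporter accumulation).  Cells with non-positive or
    missing cytoplasmic signal cannot be evaluated; they are dropped and
    reported in ``n_dropped``.
    """
    if not isinstance(cells, pd.DataFrame):
        raise G1ScreenError("g1_fraction expects a per-cell DataFrame")
    for col in ("ch_gfp_nuc", "ch_gfp_cyto"):
        if col not in cells.columns or cells[col].isna().all():
            raise MissingChannelError(f"reporter channel {col!r} absent")
    nuc = cells["ch_gfp_nuc"].to_numpy(dtype=float)
    cyt = cells["ch_gfp_cyto"].to_numpy(dtype=float)
    ok = np.isfinite(nuc) & np.isfinite(cyt) & (cyt > 0)
    n_dropped = int(len(cells) - ok.sum())
    n = int(ok.sum())
    if n == 0:
        raise G1ScreenError("no evaluable reporter cells in well")
    ratio = nuc[ok] / cyt[ok]
    if direction == "above":
        k = int(np.count_nonzero(ratio >= ratio_threshold))
    elif direction == "below":
        k = int(np.count_nonzero(ratio < ratio_threshold))
    else:
        raise G1ScreenError("direction must be 'above' or 'below'")
    plate_id = plate_id or (str(cells["plate_id"].iloc[0]) if "plate_id" in cells else "")
    well = well or (str(cells["well"].iloc[0]) if "well" in cells else "")
    return WellSummary(
        plate_id=plate_id, well=well, metric=metric, n_cells=n,
        pos_fraction=100.0 * k / n, low_cell_count=n < min_cells,
        n_dropped=n_dropped,
    )


def summarize_plate(cells: pd.DataFrame, gate: GateSpec, min_cells: int = 1500,
                    metric: str = "POS-LoRBPS780") -> pd.DataFrame:
    """Vectorized per-well responder percentages for a whole plate.

    Returns the well-summary table ``plate_id, well, metric, n_cells,
    pos_fraction, flag`` (flag = low cell count).
    """
    values = cells[gate.channel].to_numpy(dtype=float)
    finite = np.isfinite(values)
    if gate.direction == "below":
        hit = finite & (values < gate.threshold)
    else:
        hit = finite & (values >= gate.threshold)
    df = pd.DataFrame({
        "plate_id": cells["plate_id"].to_numpy(),
        "well": cells["well"].to_numpy(),
        "_finite": finite.astype(np.int64),
        "_hit": hit.astype(np.int64),
    })
    agg = df.groupby(["plate_id", "well"], sort=True, as_index=False).sum()
    if (agg["_finite"] == 0).any():
        bad = agg.loc[agg["_finite"] == 0, "well"].tolist()
        raise G1ScreenError(f"wells with zero evaluable cells: {bad}")
    out = pd.DataFrame({
        "plate_id": agg["plate_id"],
        "well": agg["well"],
        "metric": metric,
        "n_cells": agg["_finite"],
        "pos_fraction": 100.0 * agg["_hit"] / agg["_finite"],
        "flag": agg["_finite"] < min_cells,
    })
    return out


def well_summaries_frame(summaries: Sequence[WellSummary]) -> pd.DataFrame:
    """Stack :class:`WellSummary` records into the well-summary table dialect."""
    return pd.DataFrame({
        "plate_id": [s.plate_id for s in summaries],
        "well": [s.well for s in summaries],
        "metric": [s.metric for s in summaries],
        "n_cells": [s.n_cells for s in summaries],
        "pos_fraction": [s.pos_fraction for s in summaries],
        "flag": [s.low_cell_count for s in summaries],
    })
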