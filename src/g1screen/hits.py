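"""Hit calling for the primary screen.

Per-target triplicate POS values are condensed to a mean and SD; z-scores
locate each target mean within the distribution of all library target means
of the same run; targets with z below the hit cut are graded strong /
average / weak by the fold reduction of their mean POS relative to the
plate-internal mock baseline; a parallel unirradiated counterscreen flags
nonspecific hits, and per-oligonucleotide deconvolution marks validated ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import G1ScreenError

HIT_ORDER = ("strong", "average", "weak", "none")


@dataclass
class TargetResult:
    target_id: str
    replicate_pos: tuple[float, ...]
    mean_pos: float
    sd_pos: float
    z_score: float
    fold_reduction: float
    hit_class: str
    counterscreen_z: float | None = None
    validated: bool | None = None
    flags: tuple[str, ...] = ()


def z_scores(target_means: Mapping[str, float] | pd.Series) -> pd.Series:
    """Library z-scores: distance of each target mean from the population mean
    in units of the population standard deviation (all library target means of
    the same run, sample SD)."""
    means = pd.Series(target_means, dtype=float)
    if len(means) < 10:
        raise G1ScreenError("need >= 10 targets to define the population")
    mu = means.mean()
    sd = means.std(ddof=1)
    if not np.isfinite(sd):
        raise G1ScreenError("population spread undefined (non-finite means?)")
    if sd == 0:
        # zero spread only happens when every mean coincides; the limit of
        # (x - mu)/s is then 0 for every target
        return pd.Series(0.0, index=means.index, name="z_score")
    z = (means - mu) / sd
    z.name = "z_score"
    return z


def grade_hits(results: pd.DataFrame, baseline_mean: float,
               z_cut: float = -1.5,
               fold_bounds: tuple[float, float, float] = (1.4, 1.6, 2.0)) -> pd.DataFrame:
    """Grade targets by fold reduction of mean POS relative to baseline.

    ``results`` needs columns ``target_id``, ``mean_pos`` and ``z_score``.
    Adds ``fold_reduction`` (baseline / target mean) and ``hit_class``:
    strong for fold >= 2, average for [1.6, 2), weak for [1.4, 1.6) — all
    conditional on z < z_cut — and none otherwise (class boundaries closed
    on the left).
    """
    if baseline_mean <= 0:
        raise G1ScreenError("baseline mean must be positive")
    if (results["mean_pos"] <= 0).any():
        bad = results.loc[results["mean_pos"] <= 0, "target_id"].tolist()
        raise G1ScreenError(f"non-positive target means: {bad}")
    weak_b, avg_b, strong_b = fold_bounds
    out = results.copy()
    fold = baseline_mean / out["mean_pos"]
    out["fold_reduction"] = fold
    cls = np.full(len(out), "none", dtype=object)
    is_hit = out["z_score"] < z_cut
    cls[is_hit & (fold >= strong_b)] = "strong"
    cls[is_hit & (fold >= avg_b) & (fold < strong_b)] = "average"
    cls[is_hit & (fold >= weak_b) & (fold < avg_b)] = "weak"
    out["hit_class"] = cls
    return out


def counterscreen_filter(hits: pd.DataFrame,
                         unirradiated_z: Mapping[str, float] | pd.Series,
                         z_floor: float = -1.3) -> pd.DataFrame:
    """Flag hits that also score in the unirradiated counterscreen.

    Hits whose counterscreen z falls below the floor are flagged
    ``nonspecific`` and excluded from the validated candidate list
    (``candidate`` column); hits missing from the counterscreen are retained
    but flagged ``untested``.
    """
    cz = pd.Series(unirradiated_z, dtype=float)
    out = hits.copy()
    out["counterscreen_z"] = out["target_id"].map(cz)
    flags = []
    candidate = []
    for tid, hit_class, z in zip(out["target_id"], out["hit_class"],
                                 out["counterscreen_z"]):
        flag = ""
        is_hit = hit_class != "none"
        if pd.isna(z):
            flag = "untested"
            cand = is_hit
        elif z < z_floor:
            flag = "nonspecific"
            cand = False
        else:
            cand = is_hit
        flags.append(flag)
        candidate.append(cand)
    out["flags"] = flags
    out["candidate"] = candidate
    return out


def validate_deconvolution(per_oligo_results: Mapping[str, Sequence[tuple[float, float]]],
                           z_cut: float = -1.5, fold_floor: float = 1.4,
                           min_active: int = 2) -> pd.DataFrame:
    """Validate pooled hits with individual oligonucleotides.

    ``per_oligo_results[target]`` is a sequence of ``(z, fold)`` pairs, one
    per oligo.  An oligo is active when it meets the weak-or-better pool hit
    criteria (z < z_cut and fold >= fold_floor); a target validates when at
    least ``min_active`` oligos are active.  Targets with fewer than 2 tested
    oligos are flagged ``insufficient_deconvolution`` (validated = unknown).
    """
    rows = []
    for tid, oligos in per_oligo_results.items():
        n = len(oligos)
        n_active = sum(1 for z, fold in oligos if z < z_cut and fold >= fold_floor)
        if n < 2:
            rows.append((tid, n, n_active, None, "insufficient_deconvolution"))
        else:
            rows.append((tid, n, n_active, n_active >= min_active, ""))
    return pd.DataFrame(rows, columns=["target_id", "n_oligos", "n_active",
                                       "validated", "flags"])


def oligo_table_to_mapping(df: pd.DataFrame) -> dict[str, list[tuple[float, float]]]:
    """Convert a per-oligo table with columns target_id/z/fold to the mapping
    accepted by :func:`validate_deconvolution`."""
    out: dict[str, list[tuple[float, float]]] = {}
    for tid, grp in df.groupby("target_id", sort=False):
        out[tid] = list(zip(grp["z"].astype(float), grp["fold"].astype(float)))
    return out


def screen_table(well_summaries: pd.DataFrame, plate_map: pd.DataFrame,
                 baseline_role: str = "mock",
                 z_cut: float = -1.5,
                 fold_bounds: tuple[float, float, float] = (1.4, 1.6, 2.0),
                 irradiated: bool = True) -> pd.DataFrame:
    """Assemble the per-target screen table from well summaries and a plate map.

    Selects the irradiated (or unirradiated) run, collects each library
    target's replicate POS values, computes mean/SD/z, and grades hits
    against the pooled plate-internal baseline-control mean.
    """
    joined = well_summaries.merge(
        plate_map, on=["plate_id", "well"], how="inner", validate="one_to_one")
    in_run = (joined["treatment_gy"] > 0) if irradiated else (joined["treatment_gy"] == 0)
    run = joined.loc[in_run]
    if run.empty:
        raise G1ScreenError("no wells in the requested run")
    lib = run.loc[run["role"] == "library"]
    base = run.loc[run["role"] == baseline_role, "pos_fraction"]
    if base.empty:
        raise G1ScreenError(f"no baseline ({baseline_role!r}) wells in run")
    baseline_mean = float(base.mean())
    agg = lib.groupby("target_id")["pos_fraction"].agg(["mean", lambda s: s.std(ddof=1), "count"])
    agg.columns = ["mean_pos", "sd_pos", "n_replicates"]
    reps = lib.groupby("target_id")["pos_fraction"].apply(
        lambda s: tuple(round(float(v), 6) for v in s))
    table = agg.reset_index().rename(columns={"index": "target_id"})
    table["replicate_pos"] = table["target_id"].map(reps)
    table["z_score"] = z_scores(table.set_index("target_id")["mean_pos"]).to_numpy()
    table = grade_hits(table, baseline_mean, z_cut=z_cut, fold_bounds=fold_bounds)
    table.attrs["baseline_mean"] = baseline_mean
    return table
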