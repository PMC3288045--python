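"""Screen analysis orchestration: gate -> QC -> screen -> validate ->
interact -> cluster, plus the re-entrant file pipeline behind the CLI.

``analyze_screen`` turns a simulated (or loaded) screen into gates, well
summaries, QC reports and the graded, counterscreen-filtered hit table,
processing one plate at a time so memory stays bounded.  ``run_pipeline``
executes the full stage chain against an output directory, skipping stages
whose inputs (by content hash) have not changed since the last run.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim_mod
from .config import RunConfig
from .errors import G1ScreenError, StageError
from .gating import GateSpec, derive_gate, summarize_plate
from .hits import counterscreen_filter, oligo_table_to_mapping, screen_table, \
    validate_deconvolution, z_scores
from .qc import PlateSetDecision, qc_plate_set, qc_report, qc_frame
from .clustering import build_profile_matrix, cluster_targets
from .stats import survival_curves
from .io import write_table, write_newick, write_target_summary_table

_PLATE_RE = re.compile(r"^R(\d+)P(\d+)(IR|C)$")


@dataclass
class ScreenAnalysis:
    gates: dict[str, GateSpec]
    well_summaries: pd.DataFrame
    qc: pd.DataFrame
    set_decisions: list[PlateSetDecision]
    table: pd.DataFrame            # graded + counterscreen-filtered hit table
    baseline_mean: float
    counterscreen_table: pd.DataFrame | None = None

    @property
    def hits(self) -> pd.DataFrame:
        return self.table.loc[self.table["hit_class"] != "none"]

    @property
    def qc_accepted(self) -> bool:
        return all(d.accepted for d in self.set_decisions)


def _plate_key(plate_id: str) -> tuple[int, int, str]:
    m = _PLATE_RE.match(plate_id)
    if not m:
        raise G1ScreenError(f"unrecognized plate id {plate_id!r}")
    return int(m.group(1)), int(m.group(2)), m.group(3)


def analyze_screen(sim: "sim_mod.ScreenSim", cfg: RunConfig) -> ScreenAnalysis:
    """Full screen analysis of a simulated screen, plate set by plate set.

    Gates are derived per irradiated plate from its non-targeting (negative)
    and p21-siRNA (positive) control wells; the paired unirradiated plate of
    the same replicate inherits that gate, since without IR the control
    distributions do not separate.
    """
    cfg.validate()
    plate_map = sim.plate_map
    by_id = {pid: grp for pid, grp in plate_map.groupby("plate_id", sort=False)}
    gates: dict[str, GateSpec] = {}
    summaries: list[pd.DataFrame] = []
    reports = {}
    for pid in sim.plate_ids:
        rep, idx, cond = _plate_key(pid)
        if cond != "IR":
            continue
        cells = sim.cells_for_plate(pid)
        layout = by_id[pid]
        neg_wells = set(layout.loc[layout["role"] == "nt", "well"])
        pos_wells = set(layout.loc[layout["role"] == "pos", "well"])
        gate = derive_gate(
            cells.loc[cells["well"].isin(neg_wells)],
            cells.loc[cells["well"].isin(pos_wells)],
            channel="ch_marker", direction="below", params=cfg.gate)
        gates[pid] = gate
        summaries.append(summarize_plate(cells, gate, min_cells=cfg.min_cells))
        paired = f"R{rep}P{idx:02d}C"
        if paired in by_id:
            gates[paired] = gate
            cells_c = sim.cells_for_plate(paired)
            summaries.append(summarize_plate(cells_c, gate, min_cells=cfg.min_cells))
    well_summaries = pd.concat(summaries, ignore_index=True)

    # Plate QC from control wells (positive = p21 siRNA, negative = mock).
    # Only irradiated plates carry the assay window (without IR the two
    # control populations coincide by design), so QC decisions are made on
    # the irradiated run.
    merged = well_summaries.merge(plate_map, on=["plate_id", "well"], how="inner")
    for pid, grp in merged.groupby("plate_id", sort=False):
        if _plate_key(pid)[2] != "IR":
            continue
        pos_vals = grp.loc[grp["role"] == "pos", "pos_fraction"]
        neg_vals = grp.loc[grp["role"] == "mock", "pos_fraction"]
        reports[pid] = qc_report(pid, pos_vals, neg_vals,
                                 threshold=cfg.zprime_threshold)
    # triplicate plate sets: same plate index across the replicates
    sets: dict[int, list] = {}
    for pid, rep_report in reports.items():
        _, idx, _ = _plate_key(pid)
        sets.setdefault(idx, []).append(rep_report)
    decisions = [qc_plate_set(rs, threshold=cfg.zprime_threshold)
                 for _, rs in sorted(sets.items())]

    table = screen_table(well_summaries, plate_map,
                         baseline_role=cfg.baseline_role, z_cut=cfg.z_hit,
                         fold_bounds=cfg.fold_bounds, irradiated=True)
    counter = screen_table(well_summaries, plate_map,
                           baseline_role=cfg.baseline_role, z_cut=cfg.z_hit,
                           fold_bounds=cfg.fold_bounds, irradiated=False)
    counter_z = counter.set_index("target_id")["z_score"]
    table = counterscreen_filter(table, counter_z,
                                 z_floor=cfg.z_counterscreen_floor)
    return ScreenAnalysis(
        gates=gates, well_summaries=well_summaries,
        qc=qc_frame(list(reports.values())), set_decisions=decisions,
        table=table, baseline_mean=float(table.attrs["baseline_mean"]),
        counterscreen_table=counter,
    )


def analyze_well_level_screen(screen: dict, cfg: RunConfig) -> pd.DataFrame:
    """Hit table from the fast well-level simulation path.

    Same statistics as :func:`analyze_screen` (z over library means, fold vs
    pooled mock baseline, grading, counterscreen filter) without the
    per-cell gating stage.
    """
    ir = screen["ir"]
    table = pd.DataFrame({
        "target_id": ir["target_means"].index,
        "mean_pos": ir["target_means"].to_numpy(),
        "sd_pos": ir["replicates"].std(axis=1, ddof=1).to_numpy(),
    })
    table["z_score"] = z_scores(ir["target_means"]).to_numpy()
    from .hits import grade_hits
    table = grade_hits(table, ir["mock_mean"], z_cut=cfg.z_hit,
                       fold_bounds=cfg.fold_bounds)
    counter_z = z_scores(screen["c"]["target_means"])
    return counterscreen_filter(table, counter_z,
                                z_floor=cfg.z_counterscreen_floor)


# ---------------------------------------------------------------------------
# file pipeline


@dataclass
class PipelineResult:
    out_dir: Path
    analysis: ScreenAnalysis | None
    outputs: dict[str, Path] = field(default_factory=dict)
    halted_at: str | None = None


def _manifest_path(out_dir: Path) -> Path:
    return out_dir / "manifest.json"


def _load_manifest(out_dir: Path) -> dict:
    p = _manifest_path(out_dir)
    if p.exists():
        return json.loads(p.read_text())
    return {}


def _stage_fresh(manifest: dict, stage: str, input_hash: str,
                 outputs: list[Path]) -> bool:
    return manifest.get(stage) == input_hash and all(p.exists() for p in outputs)


def default_deconvolution_actives(table: pd.DataFrame) -> dict[str, int]:
    """Active-oligo plan for the deconvolution rescreen of strong and average
    pool hits: half of the strong hits confirm with 3 of 4 oligos, the rest
    and all but two average hits with a single oligo."""
    actives: dict[str, int] = {}
    strong = table.loc[table["hit_class"] == "strong", "target_id"].tolist()
    average = table.loc[table["hit_class"] == "average", "target_id"].tolist()
    for i, tid in enumerate(strong):
        actives[tid] = 3 if i < (len(strong) + 1) // 2 else 1
    for i, tid in enumerate(average):
        actives[tid] = 2 if i < 2 else 1
    return actives


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the stage chain on a synthetic screen and write the bundle.

    Stages: simulate -> gate/summarize -> qc -> screen -> validate ->
    interact -> cluster.  A rejected plate set halts the pipeline after the
    qc stage with the rejection report on disk.  Re-running with an
    unchanged config re-uses stage outputs (content-hash manifest).
    """
    cfg.validate()
    if cfg.simulation is None:
        raise StageError("simulate", "run_pipeline requires a simulation config")
    out = Path(out_dir or cfg.out_dir or "g1screen_out")
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    manifest = _load_manifest(out)
    if manifest.get("completed") == h:
        prior = {name: out / rel for name, rel in manifest.get("files", {}).items()}
        if prior and all(p.exists() for p in prior.values()):
            return PipelineResult(out_dir=out, analysis=None, outputs=prior,
                                  halted_at=manifest.get("halted"))
    outputs: dict[str, Path] = {}

    cfg.save(out / "resolved_config.json")
    log_lines = [f"config_hash={h}", f"seed={cfg.seed}",
                 f"z_hit={cfg.z_hit}", f"z_counterscreen_floor={cfg.z_counterscreen_floor}",
                 f"fold_bounds={cfg.fold_bounds}", f"zprime_threshold={cfg.zprime_threshold}"]

    sim = sim_mod.simulate_screen(cfg.simulation)
    outputs["plate_map"] = out / "plate_map.csv"
    outputs["truth_wells"] = out / "truth_wells.csv"
    outputs["truth_targets"] = out / "truth_targets.csv"
    if not _stage_fresh(manifest, "simulate", h, list(outputs.values())):
        write_table(sim.plate_map, outputs["plate_map"], config_hash=h)
        write_table(sim.truth, outputs["truth_wells"], config_hash=h)
        write_table(sim.planted, outputs["truth_targets"], config_hash=h)
        manifest["simulate"] = h

    analysis = analyze_screen(sim, cfg)

    outputs["well_summaries"] = out / "well_summaries.csv"
    outputs["gates"] = out / "gates.json"
    write_table(analysis.well_summaries, outputs["well_summaries"], config_hash=h)
    gates_payload = {
        pid: {"channel": g.channel, "threshold": g.threshold,
              "direction": g.direction, **g.derivation}
        for pid, g in analysis.gates.items()}
    (out / "gates.json").write_text(json.dumps(
        {"config": h, "gates": gates_payload}, indent=2, sort_keys=True))
    manifest["gate"] = h

    outputs["qc"] = out / "qc.csv"
    write_table(analysis.qc, outputs["qc"], config_hash=h)
    rejection = [{"plates": d.rejected_plates, "threshold": d.threshold}
                 for d in analysis.set_decisions if not d.accepted]
    (out / "qc_decisions.json").write_text(json.dumps(
        {"config": h, "accepted": analysis.qc_accepted,
         "rejections": rejection}, indent=2, sort_keys=True))
    manifest["qc"] = h
    if not analysis.qc_accepted:
        log_lines.append(f"halted=qc rejected_sets={rejection}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        manifest["completed"] = h
        manifest["halted"] = "qc"
        manifest["files"] = {name: p.name for name, p in outputs.items()}
        _manifest_path(out).write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return PipelineResult(out_dir=out, analysis=analysis,
                              outputs=outputs, halted_at="qc")

    outputs["hits"] = out / "hits.tsv"
    hit_cols = ["target_id", "mean_pos", "sd_pos", "z_score", "fold_reduction",
                "hit_class", "counterscreen_z", "flags", "candidate"]
    write_table(analysis.table[hit_cols], outputs["hits"], config_hash=h, sep="\t")
    outputs["target_summary"] = out / "target_summary.csv"
    write_target_summary_table(analysis.table, outputs["target_summary"], config_hash=h)
    manifest["screen"] = h

    # deconvolution of strong + average hits
    actives = default_deconvolution_actives(analysis.table)
    if actives:
        oligo_df = sim_mod.simulate_deconvolution(cfg.simulation, actives)
        validated = validate_deconvolution(
            oligo_table_to_mapping(oligo_df), z_cut=cfg.z_hit,
            fold_floor=cfg.fold_bounds[0])
        outputs["deconvolution"] = out / "deconvolution.tsv"
        write_table(oligo_df, outputs["deconvolution"], config_hash=h, sep="\t")
        outputs["validation"] = out / "validation.tsv"
        write_table(validated, outputs["validation"], config_hash=h, sep="\t")
    manifest["validate"] = h

    viability = sim_mod.simulate_viability_arms(cfg.simulation)
    dose_response, interactions = survival_curves(
        viability, tolerance=cfg.interaction_tolerance)
    outputs["viability"] = out / "viability.csv"
    outputs["dose_response"] = out / "dose_response.csv"
    outputs["interactions"] = out / "interactions.tsv"
    write_table(viability, outputs["viability"], config_hash=h)
    write_table(dose_response, outputs["dose_response"], config_hash=h)
    write_table(interactions, outputs["interactions"], config_hash=h, sep="\t")
    manifest["interact"] = h

    profiles = sim_mod.simulate_profile_matrix(
        sim_mod.DEFAULT_GROUPS, seed=cfg.seed)
    result = cluster_targets(profiles, k=cfg.cluster.k,
                             metric=cfg.cluster.metric, method=cfg.cluster.method,
                             row_standardize=cfg.cluster.row_standardize)
    outputs["profiles"] = out / "profile_matrix.csv"
    outputs["dendrogram"] = out / "dendrogram.nwk"
    outputs["groups"] = out / "groups.tsv"
    write_table(profiles.reset_index(names="target_id"), outputs["profiles"],
                config_hash=h)
    write_newick(result.newick, outputs["dendrogram"], config_hash=h)
    groups_df = result.groups.rename_axis("target_id").reset_index()
    write_table(groups_df, outputs["groups"], config_hash=h, sep="\t")
    manifest["cluster"] = h

    log_lines.append("halted=none")
    log_lines.append(f"n_targets={cfg.simulation.n_targets}")
    log_lines.append(f"n_hits={int((analysis.table['hit_class'] != 'none').sum())}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    manifest["completed"] = h
    manifest["halted"] = None
    manifest["files"] = {name: p.name for name, p in outputs.items()}
    _manifest_path(out).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(out_dir=out, analysis=analysis, outputs=outputs)
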