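"""Synthetic screen generator.

Produces per-cell intensity tables, plate maps, viability readouts and
phenotype-profile matrices with the statistical structure the downstream
analysis assumes, so that every stage of the pipeline can be exercised and
power-tested without instrument data.

Model summary
-------------
* Per-cell marker intensities are two-component log-normal mixtures; a
  knockdown acts on the mixture weight (the fraction of responder cells),
  never on the component locations.
* Checkpoint-competent wells shift from the unirradiated baseline responder
  fraction (default 5%) to the irradiated fraction (default 45%); a planted
  hit with effect ``e`` suppresses that shift by the fraction ``e``.
* Cell counts per well are Poisson around the configured mean, so wells
  occasionally dip below the 1500-cell QC minimum.
* The G1 reporter is a pair of independent log-normal nuclear/cytoplasmic
  signals whose location ratio encodes cell-cycle state.
* Viability is multiplicative: expected luminescence per (arm, dose) with
  log-normal read noise.

A fixed seed yields byte-identical outputs; per-plate cell tables are drawn
from seeds spawned deterministically off the master seed, so single plates
can be regenerated lazily without materializing the whole screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    VIABILITY_ARMS,
    VIABILITY_DOSES,
    PlantedHit,
    ReporterModel,
    SimulationConfig,
)
from .errors import ConfigurationError

PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = range(1, 13)

#: fixed control layout of every 96-well plate
CONTROL_WELLS = {
    "pos": ("A01", "B01", "C01"),     # p21 siRNA, full checkpoint suppression
    "mock": ("D01", "E01", "F01"),    # lipid only
    "nt": ("G01", "H01", "A12"),      # non-targeting siRNA
}

CELL_TABLE_COLUMNS = [
    "plate_id", "well", "cell_id",
    "ch_dna", "ch_marker", "ch_gfp_nuc", "ch_gfp_cyto",
]

PLATE_MAP_COLUMNS = [
    "plate_id", "well", "role", "target_id", "oligo_id", "treatment_gy", "replicate",
]

#: assay columns of the default phenotype-profile matrix (normalized to mock)
PROFILE_COLUMNS = [
    "pos_p21_ir_rel", "pos_p21_ctrl_rel", "pos_g1_ir_rel",
    "pos_lorb_ir_rel", "surv_2gy", "surv_5gy",
]

#: normalized assay patterns for the two phenotype groups: group I suppresses
#: IR-induced p21 positivity (TP53-axis), group II leaves it intact; both
#: suppress the checkpoint readouts and sensitize to IR.
DEFAULT_GROUP_PATTERNS = {
    "I": {"pos_p21_ir_rel": 0.30, "pos_p21_ctrl_rel": 0.60, "pos_g1_ir_rel": 0.55,
          "pos_lorb_ir_rel": 0.40, "surv_2gy": 0.70, "surv_5gy": 0.45},
    "II": {"pos_p21_ir_rel": 0.95, "pos_p21_ctrl_rel": 1.00, "pos_g1_ir_rel": 0.55,
           "pos_lorb_ir_rel": 0.40, "surv_2gy": 0.75, "surv_5gy": 0.50},
}

#: target -> phenotype group emulating the validated-hit panel
DEFAULT_GROUPS = {
    "PRPK": "I", "STK4": "I", "CDK4": "I", "CDKN1A": "I", "TP53": "I",
    "DYRK1A": "II", "PRKACG": "II", "HK1": "II",
}


def all_wells() -> list[str]:
    return [f"{r}{c:02d}" for r in PLATE_ROWS for c in PLATE_COLS]


def library_wells() -> list[str]:
    controls = {w for ws in CONTROL_WELLS.values() for w in ws}
    return [w for w in all_wells() if w not in controls]


def _plate_id(replicate: int, plate_idx: int, dose_gy: float) -> str:
    cond = "IR" if dose_gy > 0 else "C"
    return f"R{replicate}P{plate_idx:02d}{cond}"


def build_plate_maps(config: SimulationConfig,
                     target_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Plate maps for the full screen: irradiated run plus 0 Gy counterscreen.

    Targets are laid out one-gene-one-well in row-major order over the 87
    non-control wells of consecutive plates; each plate carries triplicate
    positive (p21 siRNA), Mock (lipid) and non-targeting control wells.  The
    whole layout is replicated ``n_replicates`` times for each treatment.
    """
    if target_ids is None:
        target_ids = [f"T{i:04d}" for i in range(1, config.n_targets + 1)]
    if len(target_ids) != config.n_targets:
        raise ConfigurationError("target_ids length must equal n_targets")
    lib_wells = library_wells()
    per_plate = len(lib_wells)
    n_plates = math.ceil(len(target_ids) / per_plate)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        for dose in (config.ir_dose_gy, 0.0):
            for p in range(1, n_plates + 1):
                pid = _plate_id(rep, p, dose)
                for role, wells in CONTROL_WELLS.items():
                    for w in wells:
                        rows.append((pid, w, role, "", "", dose, rep))
                chunk = target_ids[(p - 1) * per_plate:p * per_plate]
                for w, tid in zip(lib_wells, chunk):
                    rows.append((pid, w, "library", tid, "pool", dose, rep))
    return pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS)


def _truth_for_map(config: SimulationConfig, plate_map: pd.DataFrame) -> pd.DataFrame:
    """True responder fraction per well, from roles and planted effects."""
    effects = {h.target_id: h.effect for h in config.planted_hits}
    fracs = np.empty(len(plate_map))
    for i, (role, tid, dose) in enumerate(
            zip(plate_map["role"], plate_map["target_id"], plate_map["treatment_gy"])):
        irradiated = dose > 0
        if role == "pos":
            eff = config.pos_control_effect
        elif role in ("mock", "nt"):
            eff = 0.0
        else:
            eff = effects.get(tid, 0.0)
        fracs[i] = config.true_fraction(eff, irradiated)
    truth = plate_map.copy()
    truth["true_fraction"] = fracs
    return truth


class ScreenSim:
    """A simulated screen: plate maps, truth table and lazy per-cell tables.

    Per-cell tables are generated per plate from deterministically spawned
    child seeds, so ``cells_for_plate`` is reproducible and the full screen
    never needs to sit in memory at once.
    """

    def __init__(self, config: SimulationConfig,
                 target_ids: Sequence[str] | None = None):
        config.validate()
        self.config = config
        self.plate_map = build_plate_maps(config, target_ids)
        self.truth = _truth_for_map(config, self.plate_map)
        self.plate_ids = list(dict.fromkeys(self.plate_map["plate_id"]))
        children = np.random.SeedSequence(config.seed).spawn(len(self.plate_ids))
        self._plate_seeds = dict(zip(self.plate_ids, children))
        self._by_plate = {pid: grp.sort_values("well").reset_index(drop=True)
                          for pid, grp in self.truth.groupby("plate_id", sort=False)}

    @property
    def planted(self) -> pd.DataFrame:
        """Truth table of planted effects (one row per library target)."""
        effects = {h.target_id: (h.hit_class, h.effect) for h in self.config.planted_hits}
        lib = self.plate_map.loc[self.plate_map["role"] == "library", "target_id"]
        tids = list(dict.fromkeys(lib))
        rows = []
        for tid in tids:
            cls_name, eff = effects.get(tid, ("none", 0.0))
            rows.append((tid, cls_name, eff,
                         self.config.true_fraction(eff, irradiated=True)))
        return pd.DataFrame(rows, columns=["target_id", "hit_class", "effect",
                                           "true_ir_fraction"])

    def cells_for_plate(self, plate_id: str) -> pd.DataFrame:
        """Per-cell intensity table for one plate (regenerated on demand)."""
        if plate_id not in self._plate_seeds:
            raise KeyError(f"unknown plate {plate_id!r}")
        layout = self._by_plate[plate_id]
        rng = np.random.default_rng(self._plate_seeds[plate_id])
        im = self.config.intensity
        counts = np.maximum(1, rng.poisson(self.config.cells_per_well, size=len(layout)))
        n_total = int(counts.sum())
        responders = rng.binomial(counts, layout["true_fraction"].to_numpy())
        well_col = np.repeat(layout["well"].to_numpy(), counts)
        is_resp = np.zeros(n_total, dtype=bool)
        offset = 0
        for n, k in zip(counts, responders):
            is_resp[offset:offset + k] = True
            offset += n
        log_med = np.where(is_resp, math.log(im.lo_median), math.log(im.hi_median))
        marker = rng.lognormal(log_med, im.sigma_log)
        dna = rng.lognormal(math.log(200.0), 0.2, size=n_total)
        cell_id = np.concatenate([np.arange(1, n + 1) for n in counts])
        return pd.DataFrame({
            "plate_id": plate_id,
            "well": well_col,
            "cell_id": cell_id,
            "ch_dna": dna,
            "ch_marker": marker,
            "ch_gfp_nuc": np.nan,
            "ch_gfp_cyto": np.nan,
        })

    def cells(self, plate_ids: Iterable[str] | None = None) -> pd.DataFrame:
        """Concatenated per-cell table (use only for modest screen sizes)."""
        pids = list(plate_ids) if plate_ids is not None else self.plate_ids
        return pd.concat([self.cells_for_plate(p) for p in pids], ignore_index=True)


def simulate_screen(config: SimulationConfig,
                    target_ids: Sequence[str] | None = None) -> ScreenSim:
    """Simulate a full screen (irradiated run + unirradiated counterscreen)."""
    return ScreenSim(config, target_ids)


# ---------------------------------------------------------------------------
# fast well-level path


def simulate_well_level_screen(config: SimulationConfig,
                               rng: np.random.Generator | None = None) -> dict:
    """Sample gated well POS percentages directly, skipping per-cell draws.

    The gate of the per-cell route sits at the component-density crossing, so
    each component contributes a closed-form misclassification rate eps; a
    gated well count is then Binomial(n, p(1-eps) + (1-p) eps).  This analytic
    shortcut makes many-screen Monte Carlo affordable and is cross-checked
    against the per-cell + KDE route in the test suite.

    Returns a dict with per-target replicate POS values and means for the
    irradiated run and the counterscreen, plus pooled control means.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eps = config.intensity.misclassification_rate
    n_rep = config.n_replicates
    planted = {h.target_id: h.effect for h in config.planted_hits}
    tids = [f"T{i:04d}" for i in range(1, config.n_targets + 1)]
    effects = np.array([planted.get(t, 0.0) for t in tids])

    def draw(p_true: np.ndarray, size: tuple) -> np.ndarray:
        p_meas = p_true * (1 - eps) + (1 - p_true) * eps
        n = np.maximum(1, rng.poisson(config.cells_per_well, size=size))
        return 100.0 * rng.binomial(n, np.broadcast_to(p_meas, size)) / n

    out = {}
    for run, irradiated in (("ir", True), ("c", False)):
        p_true = np.array([config.true_fraction(e, irradiated) for e in effects])
        reps = draw(p_true[:, None], (len(tids), n_rep))
        n_ctrl_wells = 3 * max(1, math.ceil(config.n_targets / len(library_wells())))
        mock = draw(np.full((n_ctrl_wells, 1), config.true_fraction(0.0, irradiated)),
                    (n_ctrl_wells, n_rep))
        pos = draw(np.full((n_ctrl_wells, 1),
                           config.true_fraction(config.pos_control_effect, irradiated)),
                   (n_ctrl_wells, n_rep))
        out[run] = {
            "replicates": pd.DataFrame(reps, index=tids,
                                       columns=[f"rep{i+1}" for i in range(n_rep)]),
            "target_means": pd.Series(reps.mean(axis=1), index=tids, name="mean_pos"),
            "mock_mean": float(mock.mean()),
            "pos_control_mean": float(pos.mean()),
        }
    return out


# ---------------------------------------------------------------------------
# reporter wells


def simulate_reporter_well(n_cells: int, g1_fraction: float,
                           model: ReporterModel | None = None,
                           seed: int | np.random.Generator = 0,
                           plate_id: str = "SIM", well: str = "A01") -> pd.DataFrame:
    """Per-cell table for one G1-reporter well with a planted G1 fraction."""
    if not 0.0 <= g1_fraction <= 1.0:
        raise ConfigurationError("g1_fraction must lie in [0, 1]")
    model = model or ReporterModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = rng.binomial(n_cells, g1_fraction)
    is_g1 = np.zeros(n_cells, dtype=bool)
    is_g1[:k] = True
    nuc_med = np.where(is_g1, math.log(model.g1_nuc_median), math.log(model.other_nuc_median))
    cyt_med = np.where(is_g1, math.log(model.g1_cyto_median), math.log(model.other_cyto_median))
    return pd.DataFrame({
        "plate_id": plate_id,
        "well": well,
        "cell_id": np.arange(1, n_cells + 1),
        "ch_dna": rng.lognormal(math.log(200.0), 0.2, size=n_cells),
        "ch_marker": np.nan,
        "ch_gfp_nuc": rng.lognormal(nuc_med, model.sigma_log),
        "ch_gfp_cyto": rng.lognormal(cyt_med, model.sigma_log),
    })


# ---------------------------------------------------------------------------
# viability arms


def simulate_viability_arms(config: SimulationConfig,
                            arms: Sequence[str] | None = None,
                            n_bio: int = 3, n_tech: int = 3) -> pd.DataFrame:
    """Tidy ATP-luminescence table across knockdown x dose arms.

    Returns rows ``target, co_kd, dose_gy, bio_rep, tech_rep, value, assay``
    where ``target`` is "mock" or "target" and ``co_kd`` is "NT" or "coKD".
    """
    config.validate()
    arms = list(arms) if arms is not None else list(config.viability.survival)
    for arm in arms:
        if arm not in VIABILITY_ARMS:
            raise ConfigurationError(f"unknown viability arm {arm!r}")
        if arm not in config.viability.survival:
            raise ConfigurationError(f"no survival configured for arm {arm!r}")
    rng = np.random.default_rng([config.seed, 17])
    vm = config.viability
    rows = []
    for arm in arms:
        reagent, co = arm.split("/")
        for dose, frac in zip(VIABILITY_DOSES, vm.survival[arm]):
            expected = vm.base_luminescence * frac
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    noise = rng.lognormal(-0.5 * vm.noise_sigma_log ** 2,
                                          vm.noise_sigma_log)
                    rows.append((reagent, co, dose, b, t, expected * noise, "viability"))
    return pd.DataFrame(rows, columns=["target", "co_kd", "dose_gy",
                                       "bio_rep", "tech_rep", "value", "assay"])


# ---------------------------------------------------------------------------
# phenotype observations (checkpoint assays at well level)


def simulate_phenotype_observations(effects: Mapping[str, tuple[float, float]],
                                    assay: str = "POS-p21",
                                    mock_ctrl: float = 8.0, mock_ir: float = 40.0,
                                    sd_bio: float = 0.06, sd_tech: float = 0.04,
                                    n_bio: int = 3, n_tech: int = 3,
                                    co_kd: str = "none",
                                    seed: int = 0) -> pd.DataFrame:
    """Tidy per-well POS observations for mock plus knockdown conditions.

    ``effects[target] = (ctrl_rel, ir_rel)`` are multiplicative effects on the
    mock POS values without and with irradiation.  Biological replicates get a
    shared log-normal deviate (sd ``sd_bio``), technical replicates an
    independent one (sd ``sd_tech``).
    """
    rng = np.random.default_rng(seed)
    conditions = {"mock": (1.0, 1.0), **{t: tuple(v) for t, v in effects.items()}}
    rows = []
    for target, (ctrl_rel, ir_rel) in conditions.items():
        for dose, base, rel in ((0.0, mock_ctrl, ctrl_rel), (5.0, mock_ir, ir_rel)):
            for b in range(1, n_bio + 1):
                bio_dev = rng.lognormal(-0.5 * sd_bio ** 2, sd_bio)
                for t in range(1, n_tech + 1):
                    tech_dev = rng.lognormal(-0.5 * sd_tech ** 2, sd_tech)
                    rows.append((target, co_kd, dose, b, t,
                                 base * rel * bio_dev * tech_dev, assay))
    return pd.DataFrame(rows, columns=["target", "co_kd", "dose_gy",
                                       "bio_rep", "tech_rep", "value", "assay"])


# ---------------------------------------------------------------------------
# deconvolution runs


def simulate_deconvolution(config: SimulationConfig,
                           active_counts: Mapping[str, int],
                           n_oligos: int = 4, n_replicates: int = 3,
                           n_null_wells: int = 60,
                           seed_offset: int = 29) -> pd.DataFrame:
    """Per-oligo rescreen of pooled hits.

    For each target, ``active_counts[target]`` of its ``n_oligos`` individual
    oligonucleotides reproduce the pooled effect; the rest are inert.  Returns
    a table ``target_id, oligo_id, mean_pos, z, fold, truly_active``.  Because
    a deconvolution run carries few targets, z-scores are anchored on a
    population of ``n_null_wells`` effect-free (non-targeting-like) wells
    simulated alongside, mirroring the mostly-null library population that
    anchors the primary-screen z; folds are taken against mock wells.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, seed_offset])
    eps = config.intensity.misclassification_rate
    pool_effects = {h.target_id: h.effect for h in config.planted_hits}

    def well_pos(p_true: float, n_wells: int) -> np.ndarray:
        p_meas = p_true * (1 - eps) + (1 - p_true) * eps
        n = np.maximum(1, rng.poisson(config.cells_per_well, size=n_wells))
        return 100.0 * rng.binomial(n, p_meas) / n

    rows = []
    for tid, n_active in active_counts.items():
        if tid not in pool_effects:
            raise ConfigurationError(f"{tid!r} has no planted pooled effect")
        if not 0 <= n_active <= n_oligos:
            raise ConfigurationError("active count outside 0..n_oligos")
        for o in range(1, n_oligos + 1):
            active = o <= n_active
            eff = pool_effects[tid] if active else 0.0
            p_true = config.true_fraction(eff, irradiated=True)
            mean_pos = float(well_pos(p_true, n_replicates).mean())
            rows.append((tid, f"{tid}-o{o}", mean_pos, active))
    df = pd.DataFrame(rows, columns=["target_id", "oligo_id", "mean_pos", "truly_active"])
    mock_mean = float(well_pos(config.true_fraction(0.0, True), 9 * n_replicates).mean())
    null_frac = config.true_fraction(0.0, True)
    null_means = np.array([well_pos(null_frac, n_replicates).mean()
                           for _ in range(n_null_wells)])
    df["z"] = (df["mean_pos"] - null_means.mean()) / null_means.std(ddof=1)
    df["fold"] = mock_mean / df["mean_pos"]
    return df


# ---------------------------------------------------------------------------
# phenotype-profile matrices


def simulate_profile_matrix(groups: Mapping[str, str],
                            noise_sd: float = 0.08,
                            patterns: Mapping[str, Mapping[str, float]] | None = None,
                            seed: int = 0) -> pd.DataFrame:
    """Targets x assays matrix of normalized means with planted group structure.

    Each target's row is its group's assay pattern plus iid Gaussian noise of
    standard deviation ``noise_sd`` (on the normalized scale).  Default
    patterns encode the two phenotype groups: suppressed vs preserved
    IR-induced p21 positivity, both with suppressed checkpoint readouts.
    """
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 targets to build a profile matrix")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    patterns = patterns or DEFAULT_GROUP_PATTERNS
    columns: list[str] | None = None
    for g in dict.fromkeys(groups.values()):
        if g not in patterns:
            raise ConfigurationError(f"no assay pattern for group {g!r}")
        cols = list(patterns[g])
        if columns is None:
            columns = cols
        elif cols != columns:
            raise ConfigurationError("group patterns must share identical columns")
    assert columns is not None
    if len(columns) < 2:
        raise ConfigurationError("need at least 2 assay columns")
    rng = np.random.default_rng(seed)
    data = np.empty((len(groups), len(columns)))
    for i, (target, g) in enumerate(groups.items()):
        base = np.array([patterns[g][c] for c in columns])
        data[i] = base + rng.normal(0.0, noise_sd, size=len(columns))
    return pd.DataFrame(data, index=list(groups), columns=columns)
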