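"""Configuration objects for simulation and analysis runs.

All thresholds that the pipeline applies anywhere (hit z cut, counterscreen
floor, fold-grade boundaries, Z' acceptance, G1 ratio gate, minimum cell
count) live on :class:`RunConfig` so that a run is fully described by one
serializable object.  :class:`SimulationConfig` describes the synthetic
screen: plate structure, the two-component intensity model, responder
fractions with and without irradiation, planted hits, and the viability
model for the knockdown x dose survival arms.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigurationError

HIT_CLASSES = ("strong", "average", "weak")

#: survival arms of the viability assay: reagent / co-knockdown background
VIABILITY_ARMS = ("mock/NT", "target/NT", "mock/coKD", "target/coKD")

#: doses (Gy) used throughout the viability assay
VIABILITY_DOSES = (0.0, 2.0, 5.0)


@dataclass
class IntensityModel:
    """Two-component log-normal intensity model for one marker channel.

    ``lo_median``/``hi_median`` are the medians (AFU) of the responder ("low")
    and non-responder ("high") populations; ``sigma_log`` is the common
    log-scale spread.  The default spread places each component median three
    sigma away from the geometric midpoint of the two medians, i.e. the
    histogram-difference gate misclassifies ~0.13% of cells per component.
    """

    lo_median: float = 40.0
    hi_median: float = 100.0
    sigma_log: float = math.log(2.5) / 6.0

    @property
    def separation_sigmas(self) -> float:
        """Distance (in units of sigma_log) from each median to the midpoint."""
        return abs(math.log(self.hi_median / self.lo_median)) / (2.0 * self.sigma_log)

    @property
    def misclassification_rate(self) -> float:
        """Fraction of each component on the wrong side of the midpoint gate."""
        # Phi(-k) via erfc; avoids importing scipy here.
        return 0.5 * math.erfc(self.separation_sigmas / math.sqrt(2.0))

    def validate(self) -> None:
        if self.lo_median <= 0 or self.hi_median <= 0:
            raise ConfigurationError("intensity medians must be positive")
        if self.lo_median >= self.hi_median:
            raise ConfigurationError("lo_median must be below hi_median")
        if self.sigma_log <= 0:
            raise ConfigurationError("sigma_log must be positive")


@dataclass
class ReporterModel:
    """Log-normal nuclear and cytoplasmic reporter signals.

    G1 cells concentrate the reporter in the nucleus (median ratio 4), cells
    past the restriction point export it (median ratio 0.5); the nuclear and
    cytoplasmic channels are drawn independently.
    """

    g1_nuc_median: float = 120.0
    g1_cyto_median: float = 30.0
    other_nuc_median: float = 40.0
    other_cyto_median: float = 80.0
    sigma_log: float = 0.15

    def validate(self) -> None:
        for v in (self.g1_nuc_median, self.g1_cyto_median,
                  self.other_nuc_median, self.other_cyto_median):
            if v <= 0:
                raise ConfigurationError("reporter medians must be positive")
        if self.sigma_log <= 0:
            raise ConfigurationError("reporter sigma_log must be positive")


def _default_survival() -> dict[str, tuple[float, float, float]]:
    # expected luminescence relative to mock/NT at 0 Gy, per dose (0, 2, 5 Gy);
    # default scenario: target knockdown sensitizes mainly in the co-knockdown
    # (G2-checkpoint-compromised) background.
    return {
        "mock/NT": (1.00, 0.80, 0.55),
        "target/NT": (0.95, 0.72, 0.45),
        "mock/coKD": (0.90, 0.68, 0.42),
        "target/coKD": (0.85, 0.38, 0.14),
    }


@dataclass
class ViabilityModel:
    """ATP-luminescence viability model across knockdown x dose arms.

    ``survival[arm]`` holds expected luminescence relative to the mock/NT
    untreated condition at the doses in :data:`VIABILITY_DOSES`; read noise is
    multiplicative log-normal.
    """

    survival: dict[str, tuple[float, float, float]] = field(default_factory=_default_survival)
    noise_sigma_log: float = 0.05
    base_luminescence: float = 1.0e6

    def validate(self) -> None:
        for arm, fracs in self.survival.items():
            if arm not in VIABILITY_ARMS:
                raise ConfigurationError(f"unknown viability arm {arm!r}")
            if len(fracs) != len(VIABILITY_DOSES):
                raise ConfigurationError(f"arm {arm!r} needs one survival value per dose")
            if any(f <= 0 for f in fracs):
                raise ConfigurationError("survival fractions must be positive")
        if self.noise_sigma_log < 0:
            raise ConfigurationError("noise_sigma_log must be non-negative")
        if self.base_luminescence <= 0:
            raise ConfigurationError("base_luminescence must be positive")

    @classmethod
    def multiplicative_null(cls, **kw) -> "ViabilityModel":
        """Target and IR effects independent in every background (index = 0)."""
        rc, c2, c5 = 0.9, 0.80, 0.55
        surv = {
            "mock/NT": (1.0, c2, c5),
            "target/NT": (rc, rc * c2, rc * c5),
            "mock/coKD": (1.0, c2, c5),
            "target/coKD": (rc, rc * c2, rc * c5),
        }
        return cls(survival=surv, **kw)

    @classmethod
    def synergy(cls, factor: float = 0.5, **kw) -> "ViabilityModel":
        """Combined arm survives ``factor`` times the multiplicative expectation."""
        m = cls.multiplicative_null(**kw)
        rc, r2, r5 = m.survival["target/NT"]
        m.survival["target/NT"] = (rc, r2 * factor, r5 * factor)
        m.survival["target/coKD"] = (rc, r2 * factor, r5 * factor)
        return m


@dataclass
class PlantedHit:
    """A library target with a true effect on the IR-induced responder shift.

    ``effect`` in [0, 1] is the fractional suppression of the shift: 0 leaves
    the well at the competent IR responder fraction, 1 pulls it all the way
    back to the unirradiated baseline.
    """

    target_id: str
    hit_class: str
    effect: float

    def validate(self) -> None:
        if self.hit_class not in HIT_CLASSES:
            raise ConfigurationError(f"unknown hit class {self.hit_class!r}")
        if not 0.0 <= self.effect <= 1.0:
            raise ConfigurationError("hit effect must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Full description of a synthetic kinome screen."""

    seed: int
    n_targets: int = 779
    planted_hits: list[PlantedHit] = field(default_factory=list)
    cells_per_well: float = 2500.0
    intensity: IntensityModel = field(default_factory=IntensityModel)
    reporter: ReporterModel = field(default_factory=ReporterModel)
    baseline_responder_fraction: float = 0.05
    ir_responder_fraction: float = 0.45
    pos_control_effect: float = 1.0
    viability: ViabilityModel = field(default_factory=ViabilityModel)
    n_replicates: int = 3
    ir_dose_gy: float = 5.0

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")
        if self.n_targets < 1:
            raise ConfigurationError("n_targets must be >= 1")
        if self.cells_per_well <= 0:
            raise ConfigurationError("cells_per_well must be positive")
        for frac in (self.baseline_responder_fraction, self.ir_responder_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("responder fractions must lie in [0, 1]")
        if not 0.0 <= self.pos_control_effect <= 1.0:
            raise ConfigurationError("pos_control_effect must lie in [0, 1]")
        if self.ir_dose_gy < 0:
            raise ConfigurationError("doses must be non-negative")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        seen = set()
        for hit in self.planted_hits:
            hit.validate()
            if hit.target_id in seen:
                raise ConfigurationError(f"duplicate planted hit {hit.target_id!r}")
            seen.add(hit.target_id)
        self.intensity.validate()
        self.reporter.validate()
        self.viability.validate()

    # -- effect <-> fold helpers ------------------------------------------------

    def true_fraction(self, effect: float, irradiated: bool) -> float:
        """True responder fraction of a well given a knockdown effect size."""
        if not irradiated:
            return self.baseline_responder_fraction
        # convex combination: effect 0 -> competent IR fraction, 1 -> baseline
        return (1.0 - effect) * self.ir_responder_fraction + \
            effect * self.baseline_responder_fraction

    def effect_for_fold(self, fold: float) -> float:
        """Effect size whose measured POS is ``fold`` below the competent level.

        Inverts the gated (misclassification-aware) expectation so that a
        planted hit with this effect shows the requested fold reduction of the
        measured responder percentage relative to mock wells.
        """
        if fold < 1.0:
            raise ConfigurationError("fold must be >= 1")
        eps = self.intensity.misclassification_rate
        mock_meas = _measured(self.ir_responder_fraction, eps)
        target_meas = mock_meas / fold
        # invert p_meas = p (1 - eps) + (1 - p) eps
        p_true = (target_meas - eps) / (1.0 - 2.0 * eps)
        shift = self.ir_responder_fraction - self.baseline_responder_fraction
        effect = (self.ir_responder_fraction - p_true) / shift
        if not 0.0 <= effect <= 1.0:
            raise ConfigurationError(f"fold {fold} is outside the attainable range")
        return effect

    # -- (de)serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "intensity" in data and isinstance(data["intensity"], Mapping):
            data["intensity"] = IntensityModel(**data["intensity"])
        if "reporter" in data and isinstance(data["reporter"], Mapping):
            data["reporter"] = ReporterModel(**data["reporter"])
        if "viability" in data and isinstance(data["viability"], Mapping):
            via = dict(data["viability"])
            if "survival" in via:
                via["survival"] = {k: tuple(v) for k, v in via["survival"].items()}
            data["viability"] = ViabilityModel(**via)
        if "planted_hits" in data:
            data["planted_hits"] = [
                h if isinstance(h, PlantedHit) else PlantedHit(**h)
                for h in data["planted_hits"]
            ]
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(_load_config_file(path))


def reference_hits(config: SimulationConfig,
                    n_strong: int = 12, n_average: int = 18, n_weak: int = 11,
                    folds: Mapping[str, float] | None = None) -> list[PlantedHit]:
    """Planted-hit list with the reference screen structure.

    12 strong / 18 average / 11 weak hits with representative true fold
    reductions (2.5 / 1.8 / 1.5) inside each grade band, assigned to the
    first library targets in order.
    """
    folds = dict(folds or {"strong": 2.5, "average": 1.8, "weak": 1.5})
    hits: list[PlantedHit] = []
    idx = 1
    for cls_name, n in (("strong", n_strong), ("average", n_average), ("weak", n_weak)):
        eff = config.effect_for_fold(folds[cls_name])
        for _ in range(n):
            hits.append(PlantedHit(f"T{idx:04d}", cls_name, eff))
            idx += 1
    return hits


def _measured(p: float, eps: float) -> float:
    return p * (1.0 - eps) + (1.0 - p) * eps


@dataclass
class GateConfig:
    """Parameters of histogram-difference gate derivation."""

    min_control_cells: int = 500
    min_log_separation: float = 0.1
    kde_grid: int = 512
    max_kde_sample: int = 5000


@dataclass
class ClusterConfig:
    """Parameters of the phenotype-profile clustering stage."""

    k: int = 2
    metric: str = "euclidean"
    method: str = "complete"
    row_standardize: bool = True


@dataclass
class RunConfig:
    """Every threshold and knob of an analysis run, in one place."""

    seed: int = 0
    out_dir: str | None = None
    min_cells: int = 1500
    z_hit: float = -1.5
    z_strong_report: float = -2.0
    z_counterscreen_floor: float = -1.3
    fold_bounds: tuple[float, float, float] = (1.4, 1.6, 2.0)
    zprime_threshold: float = 0.2
    g1_ratio_threshold: float = 2.0
    g1_ratio_direction: str = "above"
    interaction_tolerance: float = 0.02
    baseline_role: str = "mock"
    gate: GateConfig = field(default_factory=GateConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    simulation: SimulationConfig | None = None

    def validate(self) -> None:
        if self.min_cells < 1:
            raise ConfigurationError("min_cells must be >= 1")
        lo, mid, hi = self.fold_bounds
        if not (1.0 <= lo < mid < hi):
            raise ConfigurationError("fold_bounds must be increasing and >= 1")
        if self.zprime_threshold > 1.0:
            raise ConfigurationError("Z' threshold cannot exceed 1")
        if self.g1_ratio_threshold <= 0:
            raise ConfigurationError("G1 ratio threshold must be positive")
        if self.g1_ratio_direction not in ("above", "below"):
            raise ConfigurationError("g1_ratio_direction must be 'above' or 'below'")
        if self.interaction_tolerance < 0:
            raise ConfigurationError("interaction tolerance must be non-negative")
        if self.simulation is not None:
            self.simulation.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "gate" in data and isinstance(data["gate"], Mapping):
            data["gate"] = GateConfig(**data["gate"])
        if "cluster" in data and isinstance(data["cluster"], Mapping):
            data["cluster"] = ClusterConfig(**data["cluster"])
        if "fold_bounds" in data:
            data["fold_bounds"] = tuple(data["fold_bounds"])
        if "simulation" in data and isinstance(data["simulation"], Mapping):
            data["simulation"] = SimulationConfig.from_dict(data["simulation"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(_load_config_file(path))

    def config_hash(self) -> str:
        """Stable short hash of the resolved configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(payload, fh, sort_keys=True)
            else:
                json.dump(payload, fh, indent=2, sort_keys=True, default=str)


def _load_config_file(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)
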