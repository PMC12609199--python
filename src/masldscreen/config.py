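"""Pipeline configuration: target panel, thresholds, and per-stage settings.

A single :class:`PipelineConfig` drives every stage.  Defaults mirror the
published screening protocol: activity threshold 1 uM, per-target probability
threshold 0.50, selectivity rule 0.80/0.40, break-gap mask 0.80/0.40,
structural cluster grid 0.10-0.40, and the ten-protein MASLD panel with
pathway weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
import yaml


def _data_path(name: str):
    return resources.files("masldscreen.data").joinpath(name)


def load_packaged_table(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p)


@dataclass(frozen=True)
class TargetPanel:
    """MASLD target panel: target ids, biological roles, and pathway weights
    used by the weighted total-activity score."""

    target_ids: tuple[str, ...]
    roles: dict[str, str]
    weights: dict[str, float]

    def __post_init__(self):
        for t in self.target_ids:
            w = self.weights[t]
            if not (w > 0 and w == w):
                raise ValueError(f"weight for {t} must be finite and > 0")

    @property
    def weight_vector(self):
        import numpy as np

        return np.array([self.weights[t] for t in self.target_ids])

    @classmethod
    def default(cls) -> "TargetPanel":
        df = load_packaged_table("target_panel.csv")
        return cls(
            target_ids=tuple(df["target_id"]),
            roles=dict(zip(df["target_id"], df["role"])),
            weights=dict(zip(df["target_id"], df["weight"])),
        )

    @classmethod
    def uniform(cls, target_ids) -> "TargetPanel":
        n = len(target_ids)
        return cls(
            target_ids=tuple(target_ids),
            roles={t: "" for t in target_ids},
            weights={t: 1.0 / n for t in target_ids},
        )


@dataclass
class Thresholds:
    activity_nM: float = 1000.0          # IC50 <= 1 uM encoded as active
    rse_censor: float = 0.15             # censor label when RSE exceeds 15%
    probability: float = 0.50            # per-target p(active) cut for TA
    ta_inclusive: bool = True            # p == 0.50 counts toward TA
    selectivity_max: float = 0.80
    selectivity_second: float = 0.40
    break_gap_tanimoto: float = 0.80
    break_gap_delta_p: float = 0.40
    break_gap_tan_grid: tuple = (0.75, 0.80, 0.85)
    break_gap_gap_grid: tuple = (0.30, 0.40, 0.50)

    def validate(self):
        if not (0 < self.activity_nM):
            raise ValueError("activity threshold must be positive")
        for name in ("probability", "selectivity_max", "selectivity_second",
                     "break_gap_tanimoto", "break_gap_delta_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 <= self.rse_censor <= 1.0):
            raise ValueError("rse_censor outside [0, 1]")


@dataclass
class ModelSettings:
    n_folds: int = 5
    split_kind: str = "scaffold"         # scaffold | time
    rf_trees: int = 500
    tpe_budget: int = 50
    seed: int = 17
    threshold_rule: str = "f1"           # f1 | youden  (t_opt selection)
    hl_bins: int = 10


@dataclass
class ClusterSettings:
    structural_grid: tuple = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)
    moa_grid_lo: float = 0.05
    moa_grid_hi: float = 0.50
    moa_grid_step: float = 0.05
    linkage: str = "single"              # single | complete | average
    knn_k: int = 5
    top_n_jaccard: int = 20


@dataclass
class PBPKSettings:
    grid_end_h: float = 24.0
    grid_step_h: float = 0.02
    body_mass_kg: float = 70.0
    default_ka: float = 0.8              # 1/h
    default_cl: float = 0.1              # L/h/kg
    default_f: float = 1.0
    default_ic50_uM: float = 1.0
    aggregation: str = "bliss"           # hsa | bliss
    windows: dict = field(default_factory=lambda: {
        "morning": (0.0, 12.0),
        "evening": (0.0, 12.0),
        "postprandial": (0.0, 6.0),
    })
    # chrono-window priority targets (uniform weights by default)
    window_targets: dict = field(default_factory=lambda: {
        "morning": ("FXR", "PPARA", "THRB"),
        "evening": ("PPARG", "HMGCR", "ACC1", "DGAT2"),
        "postprandial": ("LIPG", "FABP4", "FASN"),
    })


@dataclass
class FormulationSettings:
    alpha: float = 1.0                   # objective weight on TA
    beta: float = 1.0                    # objective weight on TA_weighted
    min_tanimoto_distance: float = 0.3
    portion_mass_cap_mg: float = 2000.0
    coverage_primary: float = 70.0
    coverage_tolerated: float = 50.0
    missing_limit_policy: str = "flag"   # exclude | flag


@dataclass
class PipelineConfig:
    panel: TargetPanel = field(default_factory=TargetPanel.default)
    thresholds: Thresholds = field(default_factory=Thresholds)
    model: ModelSettings = field(default_factory=ModelSettings)
    cluster: ClusterSettings = field(default_factory=ClusterSettings)
    pbpk: PBPKSettings = field(default_factory=PBPKSettings)
    formulation: FormulationSettings = field(default_factory=FormulationSettings)

    def validate(self) -> "PipelineConfig":
        self.thresholds.validate()
        if self.model.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.pbpk.aggregation not in ("hsa", "bliss"):
            raise ValueError("aggregation must be 'hsa' or 'bliss'")
        return self

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["panel"] = {
            "target_ids": list(self.panel.target_ids),
            "roles": self.panel.roles,
            "weights": self.panel.weights,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        if "panel" in raw:
            p = raw["panel"]
            cfg.panel = TargetPanel(
                target_ids=tuple(p["target_ids"]),
                roles=p.get("roles", {t: "" for t in p["target_ids"]}),
                weights=p["weights"],
            )
        for section, klass in (
            ("thresholds", Thresholds), ("model", ModelSettings),
            ("cluster", ClusterSettings), ("pbpk", PBPKSettings),
            ("formulation", FormulationSettings),
        ):
            if section in raw:
                base = getattr(cfg, section)
                for k, v in raw[section].items():
                    if isinstance(v, list):
                        v = tuple(v)
                    setattr(base, k, v)
        return cfg.validate()
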