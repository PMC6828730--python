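"""YAML run configuration for the command-line pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .imaging import SegmentationParams
from .simulate import DrugEffect, ImagingParams, SimulationConfig

__all__ = ["AnalyticsOptions", "RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class AnalyticsOptions:
    """Analytics-stage knobs: analysis window and death-calling thresholds."""

    window_start_h: float = 0.0
    window_end_h: float = 72.0
    collapse_fraction: float = 0.2
    persistence: int = 2

    @property
    def window(self) -> tuple[float, float]:
        return (self.window_start_h, self.window_end_h)


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the input paths."""

    seed: int = 0
    n_screens: int = 4
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    analytics: AnalyticsOptions = field(default_factory=AnalyticsOptions)


def _build(cls, data: Mapping[str, Any], context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} option(s): {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Build a validated RunConfig from a YAML file (all sections optional).

    Schema: top-level keys ``seed``, ``n_screens``, and sections
    ``simulation`` (with nested ``imaging`` and ``drug_effects``),
    ``segmentation``, ``analytics``. A ``seed`` argument overrides the
    file's.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    sim_raw = dict(raw.get("simulation") or {})
    imaging_raw = sim_raw.pop("imaging", None)
    effects_raw = sim_raw.pop("drug_effects", None)
    if imaging_raw is not None:
        grid = imaging_raw.get("tile_grid")
        if grid is not None:
            imaging_raw["tile_grid"] = tuple(grid)
        sim_raw["imaging"] = _build(ImagingParams, imaging_raw, "imaging")
    if effects_raw is not None:
        sim_raw["drug_effects"] = {
            str(k): _build(DrugEffect, dict(v), f"drug_effects[{k}]")
            for k, v in effects_raw.items()
        }
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        n_screens=int(raw.get("n_screens", 4)),
        simulation=_build(SimulationConfig, sim_raw, "simulation"),
        segmentation=_build(SegmentationParams, dict(raw.get("segmentation") or {}), "segmentation"),
        analytics=_build(AnalyticsOptions, dict(raw.get("analytics") or {}), "analytics"),
    )
    if seed is not None:
        cfg.seed = int(seed)
        cfg.simulation.seed = int(seed)
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the full configuration, recorded in outputs."""
    blob = json.dumps(asdict_config(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def asdict_config(cfg: RunConfig) -> dict[str, Any]:
    d = asdict(cfg)
    return d
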