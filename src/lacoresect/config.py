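"""Run configuration: one YAML document reproducing a full analysis.

A run is fully determined by its config (geometry, imaging/aperture,
event-calling, statistics and simulation blocks) plus the seed carried in
the simulation block; deterministic stages reproduce bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .event_calling import EventParams, LossParams
from .focus_quant import CylinderParams, DetectionParams
from .geometry import CassetteGeometry
from .simulate import GenotypeRateModel, SimulationConfig

__all__ = ["StatsParams", "RunConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class StatsParams:
    equal_var: bool = False
    alpha: float = 0.05


@dataclass
class RunConfig:
    geometry: CassetteGeometry = field(default_factory=CassetteGeometry)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    cylinder: CylinderParams = field(default_factory=CylinderParams)
    event: EventParams = field(default_factory=EventParams)
    stats: StatsParams = field(default_factory=StatsParams)


def _to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["simulation"]["genotype_rate_model"] = {
        k: dataclasses.asdict(v) for k, v in cfg.simulation.genotype_rate_model.items()
    }
    return d


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))
    return path


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    sim = dict(raw.get("simulation", {}))
    models = {
        k: GenotypeRateModel(**v) for k, v in sim.pop("genotype_rate_model", {}).items()
    }
    if "rad52_delay_min_range" in sim:
        sim["rad52_delay_min_range"] = tuple(sim["rad52_delay_min_range"])
    ev = dict(raw.get("event", {}))
    loss = LossParams(**ev.pop("loss", {}))
    return RunConfig(
        geometry=CassetteGeometry(**raw.get("geometry", {})),
        simulation=SimulationConfig(genotype_rate_model=models, **sim)
        if models
        else SimulationConfig(**sim),
        detection=DetectionParams(**raw.get("detection", {})),
        cylinder=CylinderParams(**raw.get("cylinder", {})),
        event=EventParams(loss=loss, **ev),
        stats=StatsParams(**raw.get("stats", {})),
    )


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonical YAML serialization."""
    canon = yaml.safe_dump(_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
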