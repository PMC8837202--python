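"""Validated pipeline configuration.

A single YAML file drives the whole pipeline.  Every physical constant
(0.59 nm/nt, Lp = 1 nm, L_prot = 8 nm, the 24-nt loading strand, the
4 eSD emitter separation, the 4-sample minimum event length, ...) is a
configurable default here, never hard-coded downstream.  Unknown keys are
rejected with a message naming the key.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .detection import DetectionConfig
from .mechanics import (
    DEFAULT_KBT,
    DEFAULT_L_PROT,
    DEFAULT_NM_PER_NT,
    DEFAULT_PERSISTENCE_LENGTH,
    TetherGeometry,
)
from .models import BellParams
from .simulate import SimulationConfig

CONFIG_SCHEMA_VERSION = 1


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Block):
    loading_nt: int = 24
    nm_per_nt: float = DEFAULT_NM_PER_NT
    L_prot: float = DEFAULT_L_PROT
    persistence_length: float = DEFAULT_PERSISTENCE_LENGTH
    kBT: float = DEFAULT_KBT

    def geometry(self, bridge_nt: int) -> TetherGeometry:
        return TetherGeometry(bridge_nt=bridge_nt, **self.model_dump())


class DetectionBlock(_Block):
    boxcar_width: int = 10
    p_trans: float = 1e-3
    emitter_separation: float = 4.0
    min_pre_samples: int = 4
    min_post_samples: int = 1
    drift_slope_esd_per_s: float = 2.0
    truncate_halfwidth_s: float = 0.5
    max_transition_span: int = 5
    step_vs_ramp_min_chi2: float = 25.0

    def detection_config(self) -> DetectionConfig:
        return DetectionConfig(**self.model_dump())


class GroupingBlock(_Block):
    axis: Literal["F_Tot", "F_Load"] = "F_Load"
    pool_constructs: bool = True


class FitBlock(_Block):
    weighting: Literal["sem", "unit"] = "sem"
    kBT: float = DEFAULT_KBT
    min_force_levels: int = 4


class BellBlock(_Block):
    kc0: float = 5.3
    xc: float = -2.0
    ks0: float = 0.01
    xs: float = 4.1

    def bell(self, kBT: float) -> BellParams:
        return BellParams(kBT=kBT, **self.model_dump())


class SimulationBlock(_Block):
    bell: BellBlock = Field(default_factory=BellBlock)
    constructs: tuple[int, ...] = (55, 70)
    sampling_rate: float = 200.0
    low_force: float = 0.5
    high_forces: tuple[float, ...] = (4.0, 6.0, 8.0, 10.0, 12.0)
    plateau_s: float = 5.0
    n_molecules: int = 4
    cycles_per_molecule: int = 25
    p_bind: float = 0.3
    noise_sd: float = 1.0
    drift_sd_nm_per_s: float = 0.5
    response_time_s: float = 0.0075

    def simulation_config(self, geom: TetherGeometry, kBT: float) -> SimulationConfig:
        data = self.model_dump(exclude={"bell", "constructs"})
        return SimulationConfig(bell=self.bell.bell(kBT), geom=geom, **data)


class PipelineConfig(_Block):
    schema_version: int = CONFIG_SCHEMA_VERSION
    seed: int = 0
    log_level: str = "INFO"
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    detection: DetectionBlock = Field(default_factory=DetectionBlock)
    grouping: GroupingBlock = Field(default_factory=GroupingBlock)
    fit: FitBlock = Field(default_factory=FitBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load and validate a YAML config; defaults apply when path is None."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)
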