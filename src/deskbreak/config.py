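"""Run configuration: one YAML file with engine / simulator / analysis sections."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError

from .engine import EngineConfig
from .simulate import ResponseModel


class SimulatorConfig(BaseModel):
    n_per_arm: int = Field(29, ge=1)
    days: int = Field(66, ge=1)
    response: ResponseModel = ResponseModel()


class AnalysisConfig(BaseModel):
    active_threshold: int = Field(10, ge=1)  # steps/min
    top_n_engaged: int = Field(6, ge=1)


class RunConfig(BaseModel):
    engine: EngineConfig = EngineConfig()
    simulator: SimulatorConfig = SimulatorConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    seed: int = Field(0, ge=0)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = self.model_dump()
        eng = data["engine"]
        eng["suitable_forecasts"] = sorted(eng["suitable_forecasts"])
        eng["unsuitable_forecasts"] = sorted(eng["unsuitable_forecasts"])
        eng["temp_range"] = list(eng["temp_range"])
        data["simulator"]["response"]["break_steps_range"] = list(
            data["simulator"]["response"]["break_steps_range"]
        )
        Path(path).write_text(yaml.safe_dump(data))
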