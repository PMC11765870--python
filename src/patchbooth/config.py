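"""Run configuration: schema-validated settings for the whole pipeline.

Defaults reproduce the reference experimental settings: tabulated-space
step 0.5 dE00 centered on Lab (50,0,0); 6^3 training / 5^3 test charts;
20 reference patches; pair offsets rho ~ N(0.6, 0.4^2) with 10 related
colors per reference; D65 as the reference illuminant.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TabGridConfig(_Section):
    center: tuple[float, float, float] = (50.0, 0.0, 0.0)
    step_de: float = Field(0.5, gt=0)
    radius: tuple[int, int, int] = (40, 40, 40)
    max_sweeps: int = Field(500, ge=0)


class ChartConfig(_Section):
    train_n: int = Field(6, ge=2)
    test_n: int = Field(5, ge=2)


class ModelConfig(_Section):
    kernel: str = "cubic"
    target_space: str = "CIEXYZ"
    smoothing: float = Field(0.0025, ge=0)
    smoothing_grid: tuple[float, ...] = (
        0.0, 1e-4, 2.5e-4, 1e-3, 2.5e-3, 1e-2, 2.5e-2, 1e-1)
    backward_sampling: int = Field(33, ge=4)

    @field_validator("kernel")
    @classmethod
    def _kernel(cls, v):
        if v not in ("linear", "cubic", "thin-plate"):
            raise ValueError(f"unknown kernel {v!r}")
        return v

    @field_validator("target_space")
    @classmethod
    def _space(cls, v):
        if v not in ("CIEXYZ", "CIELAB"):
            raise ValueError(f"unknown target space {v!r}")
        return v


class StackConfig(_Section):
    n_refs: int = Field(20, ge=1)
    center: str | tuple[float, float, float] = "gamut-centroid"
    spacing_tol: float = Field(1e-3, gt=0)


class PairConfig(_Section):
    mu: float = Field(0.6, gt=0)
    sigma: float = Field(0.4, ge=0)
    per_ref: int = Field(10, ge=1)
    outlier_threshold: float = Field(2.0, gt=0)


class PanelConfig(_Section):
    target: str = "D65"            # D65 | A
    n_steps: int = Field(10, ge=1)
    t_start: float = 30.0
    t_end: float = 45.0
    spectro_sigma_mult: float = Field(0.003, ge=0)
    drive_levels: int = Field(10, ge=2)      # characterization sweep size
    temperatures: int = Field(4, ge=2)

    @field_validator("target")
    @classmethod
    def _target(cls, v):
        if v not in ("D65", "A"):
            raise ValueError(f"unknown target illuminant {v!r}")
        return v


class PrinterRigConfig(_Section):
    noise_sigma: float = Field(0.002, ge=0)
    gamma: float = Field(1.8, gt=0)


class RunConfig(_Section):
    seed: int = 0
    out_dir: str = "runs"
    tab_grid: TabGridConfig = TabGridConfig()
    charts: ChartConfig = ChartConfig()
    model: ModelConfig = ModelConfig()
    stack: StackConfig = StackConfig()
    pairs: PairConfig = PairConfig()
    panel: PanelConfig = PanelConfig()
    printer_rig: PrinterRigConfig = PrinterRigConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def run_dir(self) -> Path:
        return Path(self.out_dir) / self.config_hash()
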