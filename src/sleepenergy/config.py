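"""Run configuration: a flat key-value file (YAML, of which JSON is a
subset) holding the model parameters plus optional strategy / sweep /
numerics blocks.  Unknown keys are rejected; defaults are the standard
parameter values."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .params import PARAM_KEYS, STANDARD, ModelParameters


class StrategyBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rho: float = Field(default=0.3, ge=0.0, le=1.0)
    mai_target: float = Field(default=0.4, ge=0.0, le=1.0)


class SweepBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mai_step: float = Field(default=0.05, gt=0.0)
    tst_step_h: float = Field(default=1.0, gt=0.0)
    rho_step: float = Field(default=0.05, gt=0.0)
    A_step: float = Field(default=0.25, gt=0.0)
    price_step: float = Field(default=0.1, gt=0.0)
    mC_values: tuple[float, ...] = (2.0, 3.5, 5.0, 6.5)


class NumericsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_steps: int = Field(default=1920, ge=64)
    bd_search_lo: float = Field(default=1e-6, gt=0.0)
    bd_search_hi: float = Field(default=50.0, gt=0.0)
    match_rtol: float = Field(default=1e-4, gt=0.0)


class RunConfig(BaseModel):
    """Validated configuration; model parameters are flat top-level keys."""

    model_config = ConfigDict(extra="forbid")

    p_W: float = STANDARD["p_W"]
    p_B1: float = STANDARD["p_B1"]
    m_C: float = STANDARD["m_C"]
    A: float = STANDARD["A"]
    TST_h: float = 8.0
    r_Ww: float = 0.5
    r_Bw: float = 0.5
    r_Ws: float = 0.5
    r_Bs: float = 0.5
    strategy: StrategyBlock = StrategyBlock()
    sweep: SweepBlock = SweepBlock()
    numerics: NumericsBlock = NumericsBlock()
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check_model_params(self) -> "RunConfig":
        # delegate invariant checks (A < m_C, non-negative rates, ...)
        self.to_params()
        return self

    def to_params(self) -> ModelParameters:
        return ModelParameters(**{k: getattr(self, k) for k in PARAM_KEYS})

    def to_flat_dict(self) -> dict:
        d = {k: getattr(self, k) for k in PARAM_KEYS}
        d["strategy"] = self.strategy.model_dump()
        d["sweep"] = dict(self.sweep.model_dump())
        d["sweep"]["mC_values"] = list(self.sweep.mC_values)
        d["numerics"] = self.numerics.model_dump()
        if self.output_dir is not None:
            d["output_dir"] = self.output_dir
        return d


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a config file; an empty or absent file gives the
    defaults.  Schema violations surface with the offending key path."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_flat_dict(), sort_keys=False))
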