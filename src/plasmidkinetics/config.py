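"""Run configuration: one YAML document driving the whole pipeline.

Unknown keys are rejected so that typos fail loudly; the document
round-trips losslessly through :meth:`RunConfig.to_yaml` /
:meth:`RunConfig.from_yaml`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .simulate import GenerationConfig

__all__ = ["RunConfig", "FitOptions", "DensitometryOptions"]


class FitOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fit_s0: bool = True
    variant: Literal["basic", "direct_break"] = "basic"
    mode: Literal["means", "lanes"] = "means"
    sd_floor_pct: float = Field(default=1.0, ge=0)
    scale_cov: bool = True
    mask_linear_above: Optional[float] = None
    xtol: float = 1e-12
    max_nfev: int = 10_000


class DensitometryOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    invert: bool = False
    baseline_method: Literal["rolling_minimum", "linear_endpoints"] = "rolling_minimum"
    baseline_window: Optional[int] = None
    migration_order: tuple[str, str, str] = ("relaxed", "linear", "supercoiled")


class RunConfig(BaseModel):
    """Top-level pipeline configuration."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    fitting: FitOptions = Field(default_factory=FitOptions)
    densitometry: DensitometryOptions = Field(default_factory=DensitometryOptions)
    simulation: Optional[GenerationConfig] = None
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        )
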