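"""Validated run configuration.

A single human-readable YAML file carries everything a batch run needs: tip
definitions, the fixed elastic parameters of the identification, processing
and inversion options, and the seed.  Every run re-emits the fully resolved
configuration next to its results together with a content hash, so results
are traceable to the exact settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from .curves import TipGeometry
from .inversion import DEFAULT_BOUNDS, FixedParameters

__all__ = ["TipConfig", "ProcessingOptions", "InversionOptions", "RunConfig"]


class TipConfig(BaseModel):
    shape: Literal["hemisphere", "pyramid", "cube_corner"]
    R_nm: float = Field(gt=0)
    beta: float | None = Field(default=None, gt=0)
    epsilon: float = Field(default=0.75, gt=0, le=1)
    area_coefficients: list[float] | None = None

    def to_geometry(self, label: str = "") -> TipGeometry:
        return TipGeometry(
            shape=self.shape,
            R_nm=self.R_nm,
            beta=self.beta,
            epsilon=self.epsilon,
            area_coefficients=(
                tuple(self.area_coefficients) if self.area_coefficients else None
            ),
            label=label,
        )


class FixedParamsConfig(BaseModel):
    """Constants of the identification sourced from literature/assumption."""

    nu_LT: float = 0.25
    nu_TT: float = 0.25
    G_LT_GPa: float = 2.51
    theta_deg: float = 0.0

    def to_fixed(self) -> FixedParameters:
        return FixedParameters(
            nu_LT=self.nu_LT, nu_TT=self.nu_TT, G_LT=self.G_LT_GPa,
            theta=self.theta_deg,
        )


class ProcessingOptions(BaseModel):
    fraction: float = Field(default=0.75, gt=0, le=1)
    machine_compliance_nm_uN: float = Field(default=0.0, ge=0)
    creep_correction: bool = True
    epsilon: float | None = Field(default=None, gt=0, le=1)


class InversionOptions(BaseModel):
    E_L_bounds_GPa: tuple[float, float] = DEFAULT_BOUNDS[0]
    E_T_bounds_GPa: tuple[float, float] = DEFAULT_BOUNDS[1]
    n_starts: int = Field(default=5, ge=1)

    @field_validator("E_L_bounds_GPa", "E_T_bounds_GPa")
    @classmethod
    def _ordered(cls, v):
        if not 0 < v[0] < v[1]:
            raise ValueError(f"bounds must satisfy 0 < lo < hi, got {v}")
        return v

    @property
    def bounds(self):
        return (tuple(self.E_L_bounds_GPa), tuple(self.E_T_bounds_GPa))


DEFAULT_TIPS = {
    "hemisphere": TipConfig(shape="hemisphere", R_nm=300.0),
    "pyramid": TipConfig(shape="pyramid", R_nm=100.0),
    "cube_corner": TipConfig(shape="cube_corner", R_nm=40.0),
}


class RunConfig(BaseModel):
    """Top-level configuration of a full pipeline run."""

    tips: dict[str, TipConfig] = Field(default_factory=lambda: dict(DEFAULT_TIPS))
    fixed: FixedParamsConfig = FixedParamsConfig()
    processing: ProcessingOptions = ProcessingOptions()
    inversion: InversionOptions = InversionOptions()
    summary_methods: list[Literal["mean", "median"]] = ["mean", "median"]
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
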