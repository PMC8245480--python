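"""Validated pipeline configuration (pydantic models, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConstantsConfig(_Strict):
    aragonite_density: float = Field(2.93, gt=0)
    caco3_molar_mass: float = Field(100.0869, gt=0)
    carbon_molar_mass: float = Field(12.011, gt=0)
    hours_per_year: float = Field(8760.0, gt=0)
    rate_umol_cm2_yr: float = Field(1773.97, gt=0)
    rate_se_umol_cm2_yr: float = Field(324.35, ge=0)
    mat_fraction: float = Field(0.9277, ge=0, le=1)
    n_seeps: int = Field(10_000, ge=1)
    precip_central_mol_yr: float = Field(1.7e12, gt=0)
    precip_low_mol_yr: float = Field(0.6e12, gt=0)
    precip_high_mol_yr: float = Field(3.6e12, gt=0)

    @model_validator(mode="after")
    def _precip_ordered(self):
        if not self.precip_low_mol_yr <= self.precip_central_mol_yr <= self.precip_high_mol_yr:
            raise ValueError("precipitation fluxes must satisfy low <= central <= high")
        return self


class OptionsConfig(_Strict):
    mass_for_area: str = "mean"  # initial | final | mean
    force_origin: bool = False
    calibration_form: str = "sigmoid"  # sigmoid | linear
    clamp_out_of_range: bool = False
    kymograph_averaging: str = "ratio"  # ratio | intensity
    se_rule: str = "mean"  # mean | quadrature


class RatesStage(_Strict):
    coupons: Path
    out: Path


class UpscaleStage(_Strict):
    sites: Path | None = None  # None -> packaged literature table
    out: Path


class CoverageStage(_Strict):
    rois: Path
    scalebars: dict
    out: Path


class PhmapStage(_Strict):
    stack_npz: Path
    calibration: Path
    kymograph: dict
    out_prefix: Path


class StagesConfig(_Strict):
    rates: RatesStage | None = None
    phmap: PhmapStage | None = None
    coverage: CoverageStage | None = None
    upscale: UpscaleStage | None = None


class PipelineConfig(_Strict):
    """Top-level configuration for `seepflux run`."""

    seed: int = 0
    verbosity: int = 1
    constants: ConstantsConfig = Field(default_factory=ConstantsConfig)
    options: OptionsConfig = Field(default_factory=OptionsConfig)
    stages: StagesConfig = Field(default_factory=StagesConfig)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
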