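"""Pipeline configuration: one validated schema for every stage."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator


class MabConfig(BaseModel):
    name: str = "mAb1"
    light_chain_isotype: str = "kappa"
    include_sefl: bool = True
    fasta_path: str | None = None  # LC/HC records; None -> built-in example
    registry_path: str | None = None

    @field_validator("light_chain_isotype")
    @classmethod
    def _isotype(cls, v: str) -> str:
        if v not in ("kappa", "lambda"):
            raise ValueError("light_chain_isotype must be 'kappa' or 'lambda'")
        return v


class DesignConfig(BaseModel):
    timepoints_min: list[float] = [0, 1, 5, 10, 15, 30, 60]
    dtt_mm: float = 1.0
    replicates: int = Field(1, ge=1)


class NoiseConfig(BaseModel):
    area_cv: float = Field(0.05, ge=0)
    ppm_jitter_sd: float = Field(1.5, ge=0)
    idotp_range: tuple[float, float] = (0.92, 1.0)


class TruthConfig(BaseModel):
    # k = sasa_slope * SASA per site, except for class_rate_overrides.
    sasa_slope: float = Field(1.6e-4, gt=0)
    f0: float = Field(0.01, ge=0, lt=1)
    class_sasa: dict[str, float] | None = None
    class_rate_overrides: dict[str, float] | None = None  # None -> hinge default
    sasa_jitter_sd: float = Field(0.25, ge=0)


class QcConfig(BaseModel):
    max_ppm: float = Field(5.0, gt=0)
    min_idotp: float = Field(0.9, ge=0, le=1)
    hinge_per_site: bool = False


class KineticsConfig(BaseModel):
    method: str = "log_linear"
    saturation_floor: float = Field(0.01, gt=0, lt=1)
    n_bootstrap: int = Field(0, ge=0)

    @field_validator("method")
    @classmethod
    def _method(cls, v: str) -> str:
        if v not in ("log_linear", "per_timepoint_mean"):
            raise ValueError("method must be 'log_linear' or 'per_timepoint_mean'")
        return v


class SasaConfig(BaseModel):
    probe_radius: float = Field(1.4, gt=0)
    n_points: int = Field(960, ge=12)
    trajectory_path: str | None = None  # multi-model PDB; None -> skip real SASA


class StiffnessConfig(BaseModel):
    # Cystine-model Langevin run used as the fixture trajectory.
    md_steps: int = Field(100_000, ge=1000)
    md_stride: int = Field(50, ge=1)
    md_equilibration_steps: int = Field(10_000, ge=0)
    temperature: float = Field(300.0, gt=0)


class CorrelateConfig(BaseModel):
    exclude_classes: list[str] = ["hinge"]
    log_log: bool = False


class PipelineConfig(BaseModel):
    seed: int = 0
    outdir: str = "results"
    mab: MabConfig = MabConfig()
    design: DesignConfig = DesignConfig()
    noise: NoiseConfig = NoiseConfig()
    truth: TruthConfig = TruthConfig()
    qc: QcConfig = QcConfig()
    kinetics: KineticsConfig = KineticsConfig()
    sasa: SasaConfig = SasaConfig()
    stiffness: StiffnessConfig = StiffnessConfig()
    correlate: CorrelateConfig = CorrelateConfig()

    def config_hash(self) -> str:
        # outdir is deployment detail, not science: identical analyses hash
        # identically wherever their artifacts land
        payload = json.dumps(self.model_dump(exclude={"outdir"}),
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def validate_paths(self) -> None:
        for label, path in (
            ("mab.fasta_path", self.mab.fasta_path),
            ("mab.registry_path", self.mab.registry_path),
            ("sasa.trajectory_path", self.sasa.trajectory_path),
        ):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path} does not exist")


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        return PipelineConfig.model_validate(json.load(fh))
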