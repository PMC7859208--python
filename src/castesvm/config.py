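"""Pipeline configuration: YAML-backed, validated with pydantic.

A single master seed fans out deterministically to per-stage seeds (derived
by hashing the stage name, not Python's randomized ``hash``), so any stage
can be re-run in isolation with the same randomness as inside ``run-all``.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["PipelineConfig", "stage_seed", "load_config"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


class SimulateConfig(BaseModel):
    enabled: bool = True
    n_genes: int = 500
    n_informative: int = 50
    n_age_genes: int = 50
    n_queens: int = 26
    n_workers: int = 12
    n_qr: int = 58
    caste_effect: float = 1.5
    age_effect: float = 1.0
    dispersion: float = 0.1
    depth_mean: float = 1e6
    depth_cv: float = 0.25
    t_age_correlation: float = 0.48
    phenotype_noise_sd: float = Field(0.15, ge=0)


class PathsConfig(BaseModel):
    counts: str | None = None
    samples: str | None = None


class SVMConfig(BaseModel):
    kernel: str = "radial"
    #: null -> study-scaled gamma (resolves to 1e-6 at the study's 10,734 genes)
    gamma: float | None = None
    degree: int = 3
    coef0: float = 0.0
    C: float = 2.0 ** 5
    epsilon: float = Field(0.1, ge=0)

    @field_validator("kernel")
    @classmethod
    def _known_kernel(cls, v):
        allowed = {"radial", "linear", "sigmoid", "polynomial"}
        if v not in allowed:
            raise ValueError(f"kernel must be one of {sorted(allowed)}")
        return v


class GridConfig(BaseModel):
    enabled: bool = False
    n_points_c: int = 5
    n_points_gamma: int = 5


class RFEConfig(BaseModel):
    k: int = 3
    repeats: int = 20
    stop_size: int = 100


class DEConfig(BaseModel):
    lfc_threshold: float = Field(default_factory=lambda: math.log2(1.5), ge=0)
    alpha: float = Field(0.05, gt=0, lt=1)


class PhenotypeConfig(BaseModel):
    ridge: float = Field(0.0, ge=0)


class PipelineConfig(BaseModel):
    """Full run-all configuration with the documented operating point as default."""

    seed: int = 0
    outdir: str = "results/run"
    simulate: SimulateConfig = SimulateConfig()
    paths: PathsConfig = PathsConfig()
    preprocessing_pseudocount: float = Field(1.0, ge=0)
    svm: SVMConfig = SVMConfig()
    grid: GridConfig = GridConfig()
    rfe: RFEConfig = RFEConfig()
    de: DEConfig = DEConfig()
    phenotypes: PhenotypeConfig = PhenotypeConfig()

    model_config = {"extra": "forbid"}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config file, applying flat ``section.key`` overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for key, value in (overrides or {}).items():
        target = data
        parts = key.split(".")
        for part in parts[:-1]:
            target = target.setdefault(part, {})
        target[parts[-1]] = value
    return PipelineConfig.model_validate(data)


def write_default_config(path) -> None:
    cfg = PipelineConfig()
    Path(path).write_text(cfg.to_yaml())
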