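"""Run configuration: schema-validated settings for the whole pipeline.

A single master seed derives every stage seed deterministically (hash of
master seed, stage name and species id), so adding a species never perturbs
the results of existing species.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    n_rows: int = Field(100, ge=1)
    n_cols: int = Field(100, ge=1)
    cell_size_km: float = Field(1.0, gt=0)


class ClimateConfig(_Strict):
    correlation_length_km: float = Field(10.0, gt=0)
    bio1_mean: float = 15.0
    bio1_spread: float = 8.0
    bio3_mean: float = 45.0
    bio3_spread: float = 10.0
    temp_offset_mean: float = 10.0
    temp_offset_spread: float = 4.0
    bio12_median: float = 1200.0
    bio12_log_sd: float = 0.4
    bio18_fraction_mean: float = Field(0.35, gt=0, lt=1)


class ScenarioConfig(_Strict):
    label: str = "future_rcp45"
    additive: dict[str, float] = Field(
        default_factory=lambda: {"BIO1": 2.4, "BIO5": 2.8, "BIO6": 2.0, "BIO3": 1.0}
    )
    multiplicative: dict[str, float] = Field(
        default_factory=lambda: {"BIO12": 0.9, "BIO18": 0.85}
    )
    noise_sd: dict[str, float] = Field(default_factory=dict)
    pa_damping: float = Field(0.5, ge=0, le=1)


class SpeciesConfig(_Strict):
    n_species: int = Field(10, ge=1)
    niche_sigma: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"BIO1": (1.5, 3.0), "BIO12": (250.0, 600.0)}
    )
    optimum_quantile_range: tuple[float, float] = (0.2, 0.8)
    presence_threshold: float = Field(0.5, gt=0, lt=1)
    n_occurrences: int = Field(1000, ge=1)
    min_range_cells: int = Field(50, ge=1)
    effort_bias: str = "none"  # 'none' or 'westward'
    threatened_fraction: float = Field(0.25, ge=0, le=1)

    @field_validator("effort_bias")
    @classmethod
    def _bias(cls, v: str) -> str:
        if v not in ("none", "westward"):
            raise ValueError("effort_bias must be 'none' or 'westward'")
        return v


class PAConfig(_Strict):
    target_fraction: float = Field(0.15, gt=0, lt=1)
    n_patches: int = Field(25, ge=1)
    class_mix: dict[str, float] = Field(
        default_factory=lambda: {"Ia": 0.1, "Ib": 0.1, "II": 0.3, "III": 0.1,
                                 "IV": 0.2, "V": 0.1, "VI": 0.1}
    )
    placement: str = "stable-climate"

    @field_validator("placement")
    @classmethod
    def _placement(cls, v: str) -> str:
        if v not in ("uniform", "stable-climate"):
            raise ValueError("placement must be 'uniform' or 'stable-climate'")
        return v


class PartitionConfig(_Strict):
    k_regions: int = Field(6, ge=1)
    k_countries: int = Field(12, ge=1)


class PrepConfig(_Strict):
    buffer_km: float = Field(400.0, ge=0)
    min_records: int = Field(5, ge=1)
    min_year: int | None = None
    max_year: int | None = None


class SDMConfig(_Strict):
    algorithms: tuple[str, ...] = ("GLM", "GBM", "MaxEnt", "RF", "SVM")
    learner_params: dict[str, dict] = Field(default_factory=dict)
    n_pseudo_absence: int | None = None
    retention_min: float = Field(0.7, ge=-1, le=1)
    train_frac: float = Field(0.7, gt=0, lt=1)
    n_rep: int = Field(5, ge=1)
    calibration_buffer_km: float = Field(500.0, ge=0)
    vif_threshold: float = Field(10.0, gt=1)
    vif_sample_cells: int = Field(10_000, ge=10)


class AnalysisConfig(_Strict):
    benchmarks: tuple[float, ...] = (0.15, 0.30)
    top_frac: float = Field(0.2, gt=0, lt=1)
    bottom_frac: float = Field(0.2, gt=0, lt=1)
    pa_subset: str = "strict"

    @field_validator("pa_subset")
    @classmethod
    def _subset(cls, v: str) -> str:
        if v not in ("strict", "all"):
            raise ValueError("pa_subset must be 'strict' or 'all'")
        return v


class RunConfig(_Strict):
    """Top-level, fully-defaulted pipeline configuration."""

    grid: GridConfig = Field(default_factory=GridConfig)
    climate: ClimateConfig = Field(default_factory=ClimateConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    species: SpeciesConfig = Field(default_factory=SpeciesConfig)
    pa: PAConfig = Field(default_factory=PAConfig)
    partition: PartitionConfig = Field(default_factory=PartitionConfig)
    prep: PrepConfig = Field(default_factory=PrepConfig)
    sdm: SDMConfig = Field(default_factory=SDMConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int = Field(0, ge=0)
    output_dir: str = "sdmgap_run"

    def config_hash(self) -> str:
        doc = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def validate_config(raw: dict | str | Path) -> RunConfig:
    """Parse and validate a config document (dict, YAML/JSON text, or path)."""
    if isinstance(raw, (str, Path)):
        p = Path(raw)
        text = p.read_text() if p.exists() else str(raw)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config document must be a mapping")
    return RunConfig.model_validate(raw)


def stage_seed(master_seed: int, stage: str, extra: str = "") -> int:
    """Deterministic per-stage (and per-species) seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stage}:{extra}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
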