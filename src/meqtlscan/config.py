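"""Validated configuration models for simulation, QC and the pipeline driver."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class PlantedEffect(BaseModel):
    """One planted SNP->CpG effect: an additive shift in methylation beta per
    minor-allele copy, optionally restricted to one sample group."""

    snp_index: int = Field(ge=0)
    cpg_index: int = Field(ge=0)
    delta_per_allele: float
    stratum: Literal["all", "case_only", "control_only"] = "all"


class SimulationConfig(BaseModel):
    """Parameters of the synthetic genotype + methylation generator.

    Defaults emulate the geometry of a 450K case/control methylation study:
    689 samples (354 cases, 335 controls), 62 biallelic SNP probes, uniform
    ages, and a three-peaked SNP-probe signal around beta 0, 0.5, 1.
    ``n_cpgs`` defaults to a desk-scale 5,000 sites; the array-scale 485,512
    is supported but only sensible for metadata-level (dry-run) work.
    """

    n_samples: int = Field(default=689, ge=10)
    case_fraction: float = Field(default=354 / 689, gt=0.0, lt=1.0)
    n_snps: int = Field(default=62, ge=1)
    n_cpgs: int = Field(default=5000, ge=1)
    allele_freq_range: Tuple[float, float] = (0.05, 0.5)
    probe_noise_sd: float = Field(default=0.03, ge=0.0)
    # None -> bimodal hypo/hyper/intermediate mixture of Beta shapes typical
    # of array methylation; a pair (a, b) applies one shape to every CpG.
    baseline_beta_params: Optional[Tuple[float, float]] = None
    effect_table: list[PlantedEffect] = Field(default_factory=list)
    age_range: Tuple[float, float] = (18.0, 70.0)
    age_effect_sd: float = Field(default=0.002, ge=0.0)
    missing_probe_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    seed: int = 0

    @field_validator("allele_freq_range")
    @classmethod
    def _check_freq_range(cls, v: Tuple[float, float]) -> Tuple[float, float]:
        lo, hi = v
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(
                "allele_freq_range must satisfy 0 < low <= high <= 0.5"
            )
        return v

    @field_validator("age_range")
    @classmethod
    def _check_age_range(cls, v: Tuple[float, float]) -> Tuple[float, float]:
        lo, hi = v
        if not (0.0 < lo <= hi):
            raise ValueError("age_range must be positive with low <= high")
        return v

    @field_validator("baseline_beta_params")
    @classmethod
    def _check_beta_params(cls, v):
        if v is not None and (v[0] <= 0 or v[1] <= 0):
            raise ValueError("baseline_beta_params shapes must be positive")
        return v

    @model_validator(mode="after")
    def _check_effects(self) -> "SimulationConfig":
        seen = set()
        for eff in self.effect_table:
            if eff.snp_index >= self.n_snps:
                raise ValueError(
                    f"effect_table: snp_index {eff.snp_index} out of range "
                    f"for n_snps={self.n_snps}"
                )
            if eff.cpg_index >= self.n_cpgs:
                raise ValueError(
                    f"effect_table: cpg_index {eff.cpg_index} out of range "
                    f"for n_cpgs={self.n_cpgs}"
                )
            key = (eff.snp_index, eff.cpg_index)
            if key in seen:
                raise ValueError(f"effect_table: duplicate planted pair {key}")
            seen.add(key)
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


class QcThresholds(BaseModel):
    """SNP-level quality filters. A SNP passes when MAF > maf_min, missing
    rate < missing_max, and the HWE exact p-value > hwe_p_min — all strict."""

    maf_min: float = Field(default=0.01, ge=0.0, le=1.0)
    missing_max: float = Field(default=0.01, ge=0.0, le=1.0)
    hwe_p_min: float = Field(default=0.001, ge=0.0, le=1.0)


class PipelineConfig(BaseModel):
    """End-to-end driver configuration (paths plus analysis settings)."""

    methylation: Path
    samples: Path
    probes: Optional[Path] = None       # raw SNP-probe signal (to be called)
    genotypes: Optional[Path] = None    # pre-called dosage codes
    snp_bed: Optional[Path] = None
    cpg_bed: Optional[Path] = None
    out_dir: Path
    qc: QcThresholds = Field(default_factory=QcThresholds)
    alpha: float = Field(default=0.05, ge=0.0, lt=1.0)
    window: int = Field(default=1_000_000, gt=0)
    fdr_scope: Literal["per_snp", "global"] = "per_snp"
    max_cluster_distance: float = Field(default=0.2, gt=0.0)
    hwe_group: Literal["all", "case", "control"] = "all"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_genotype_source(self) -> "PipelineConfig":
        if (self.probes is None) == (self.genotypes is None):
            raise ValueError("exactly one of 'probes' or 'genotypes' must be set")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})
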