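"""Pipeline configuration: every stage threshold in one validated object.

Defaults are the analysis conventions used throughout the package:
|log2FC| > 1 (mRNA) / > 0.5 (protein) with BH-adjusted p < 0.01,
synergy hits at sDSS > 5 with curve-fit SE <= 19 and activity
threshold 10%, ChIP consensus at >= 4 of 7 experiments, ORA at
FDR < 0.05.  Unknown keys are rejected; a config round-trips through
YAML unchanged and hashes stably for output provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_genes_protein: int = Field(2000, gt=0)
    n_genes_mrna: int = Field(5000, gt=0)
    psm_per_gene: float = Field(3.0, gt=0)
    psm_noise_sd: float = Field(0.2, ge=0)
    count_dispersion: float = Field(0.05, ge=0)
    n_de_genes: int = Field(200, ge=0)
    de_log2fc: float = Field(2.0)
    n_compounds: int = Field(528, gt=0)
    n_synergists: int = Field(17, ge=0)
    screen_noise_sd: float = Field(5.0, ge=0)
    synergy_shift: float = Field(-1.5)
    n_chip_experiments: int = Field(7, gt=0)
    n_consensus_genes: int = Field(150, ge=0)
    chip_background_rate: float = Field(0.1, ge=0, le=1)
    n_gene_sets: int = Field(20, gt=0)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    mrna_lfc_cutoff: float = Field(1.0, gt=0)
    protein_lfc_cutoff: float = Field(0.5, gt=0)
    p_adj_cutoff: float = Field(0.01, gt=0, le=1)
    sdss_cutoff: float = Field(5.0)
    se_cutoff: float = Field(19.0, ge=0)
    activity_threshold: float = Field(10.0, ge=0, lt=100)
    min_chip_experiments: int = Field(4, ge=1)
    ora_fdr: float = Field(0.05, gt=0, le=1)
    fdr_protein: float = Field(0.01, gt=0, le=1)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
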