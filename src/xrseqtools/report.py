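"""Machine-readable run report and pipeline configuration.

Both are pydantic models with ``extra="forbid"`` so unknown keys are
rejected on load. The JSON Schema shipped at ``report_schema.json`` inside
the package is the generated schema of :class:`RunReport`; reports written
by the CLI validate against it.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class FilterParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_len: int = 24
    max_len: int = 29
    min_overlap: int = 3


class ProfileParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_bins: int = 100
    min_gene_length: int = 5000
    min_gap: int = 5000
    promoter_span: int = 1000
    downstream_span: int = 1000
    stratum_length: int = 26


class QuantParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bootstrap_reps: int = 1000
    reference_genotype: str = "WT"


class GeneratorParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_chroms: int = 2
    chrom_len: int = 300_000
    n_genes: int = 24
    gene_len_min: int = 5_500
    gene_len_max: int = 9_000
    min_gap: int = 5_200
    damage_rate: float = 0.1
    damage_type: str = "CPD"
    spike_quantity: int = 2000
    spike_damage_rate: float = 0.08
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    offset5_probs: dict[int, float] = Field(
        default_factory=lambda: {19: 0.70, 20: 0.20, 21: 0.10}
    )
    offset3_probs: dict[int, float] = Field(
        default_factory=lambda: {5: 0.80, 6: 0.20}
    )
    nibble3_probs: dict[int, float] = Field(
        default_factory=lambda: {0: 0.85, 1: 0.10, 2: 0.05}
    )


class PipelineConfig(BaseModel):
    """Validated configuration for the CLI; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "xrseq_out"
    preset: str = "five-genotypes"
    filter: FilterParams = Field(default_factory=FilterParams)
    profile: ProfileParams = Field(default_factory=ProfileParams)
    quant: QuantParams = Field(default_factory=QuantParams)
    generator: GeneratorParams = Field(default_factory=GeneratorParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)


class StageCountsReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_input: int
    n_trimmed: int
    n_deduplicated: int
    n_with_n_dropped: int
    n_aligned_unique: int
    n_multi_hit: int
    n_no_hit: int
    n_filtered: int


class SampleReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sample_id: str
    genotype: str
    stages: StageCountsReport
    n_target: int
    n_spike: int
    target_spike_ratio: float
    median_length: float
    ts_nts_ratio: float | None
    genome_distribution: dict[str, float]
    relative_repair_percent: float | None = None
    relative_repair_ci: tuple[float, float] | None = None


class RunReport(BaseModel):
    """Top-level machine-readable result bundle of ``xrseq report``."""

    model_config = ConfigDict(extra="forbid")
    seed: int
    reference_sample: str
    samples: list[SampleReport]


def report_schema() -> dict:
    """The published JSON Schema for :class:`RunReport`."""
    return RunReport.model_json_schema()


def packaged_schema() -> dict:
    with resources.files("xrseqtools").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(data: dict) -> RunReport:
    """Parse-and-validate a report dict against the model (raises on error)."""
    return RunReport.model_validate(data)
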