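"""Locus and pipeline configuration.

``LocusConfig`` is the coordinate frame for every long-read stage: the
plus-strand repeat unit, the 5' counting anchor immediately upstream of the
tract, the start of the 3' flank, the filtering thresholds, and the
heterozygous SNPs used for allele phasing.  Configurations are pydantic
models so they serialise losslessly to YAML/JSON and back.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class SnpDef(BaseModel):
    """A phase-informative (or merely observed) SNP in the locus flanks.

    ``template_position`` is a 0-based plus-strand coordinate on the
    unedited reference template.  ``ref_allele``/``alt_allele`` name which
    allele carries which base, so a per-read genotype maps to an allele
    label (the phased SNP marks the WT allele in an expansion carrier).
    """

    snp_id: str
    template_position: int = Field(ge=0)
    ref_base: str
    alt_base: str
    phased_informative: bool = True
    ref_allele: str = "allele1"
    alt_allele: str = "allele2"

    @model_validator(mode="after")
    def _distinct_bases(self) -> "SnpDef":
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        return self


class LocusConfig(BaseModel):
    """Repeat locus definition and per-read filter thresholds."""

    repeat_unit: str = "GGGGCC"
    anchor5: str = "CGCCC"
    anchor3: str = ""
    min_passes: int = Field(default=3, ge=1)
    max_unit_edit_distance: int = Field(default=1, ge=0)
    termination_run: int = Field(default=3, ge=1)
    anchor_max_mismatches: int = Field(default=1, ge=0)
    snps: list[SnpDef] = Field(default_factory=list)
    # Reference flank sequences: left_flank ends with anchor5, right_flank
    # starts with anchor3.  Needed for SNP probe alignment and excision
    # landmark placement; optional for pure repeat counting.
    left_flank: str = ""
    right_flank: str = ""

    @field_validator("repeat_unit")
    @classmethod
    def _unit_len(cls, v: str) -> str:
        if len(v) != 6:
            raise ValueError("repeat_unit must be 6 nt")
        return v.upper()

    @model_validator(mode="after")
    def _check_flanks(self) -> "LocusConfig":
        if self.left_flank and not self.left_flank.endswith(self.anchor5):
            raise ValueError("left_flank must end with the 5' anchor")
        if self.right_flank:
            if not self.anchor3:
                self.anchor3 = self.right_flank[:12]
            elif not self.right_flank.startswith(self.anchor3):
                raise ValueError("right_flank must start with anchor3")
        return self

    @property
    def tract_start(self) -> int:
        """Template coordinate of the first repeat base (= 5' flank length)."""
        return len(self.left_flank)


class Thresholds(BaseModel):
    min_reads_per_allele: int = Field(default=5, ge=1)
    min_mode_gap: int = Field(default=5, ge=1)
    min_outcome_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    retained_min_repeats: int = Field(default=50, ge=1)
    ddpcr_min_positive_droplets: int = Field(default=10, ge=0)
    msd_ratio_threshold: float = Field(default=1.5, gt=0.0)


class PipelineConfig(BaseModel):
    """End-to-end run configuration consumed by :func:`pipeline.run_pipeline`."""

    locus: LocusConfig = Field(default_factory=LocusConfig)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    seed: int = 0
    reads: Optional[str] = None            # FASTA/FASTQ/BAM of CCS reads
    templates: dict[str, str] = Field(default_factory=dict)  # allele -> FASTA
    droplets_csv: Optional[str] = None
    msd_csv: Optional[str] = None
    out_dir: str = "c9quant_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))
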