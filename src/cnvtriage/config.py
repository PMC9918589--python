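"""Run configuration: one flat key-value (YAML) file naming every input
path and every threshold used anywhere in the pipeline.  Unknown keys are
rejected so that typos fail loudly instead of silently running defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .evidence import (
    DEFAULT_BREAKPOINT_TOLERANCE,
    DEFAULT_LOWER_PCT,
    DEFAULT_N_BINS,
    DEFAULT_UPPER_PCT,
)
from .filtration import DEFAULT_AF_THRESHOLD
from .inheritance import DEFAULT_MIN_RECIPROCAL
from .prioritization import ScoreConfig

__all__ = ["RunConfig", "CONFIG_TEMPLATE"]

GENOME_BUILDS = ("hg19", "hg38")


@dataclass
class RunConfig:
    # inputs
    cnv_path: str = ""
    cnv_dialect: str = "bed_tsv"  # bed_tsv | vcf
    sample_id: str = "SAMPLE"
    family_id: str = ""
    annodir: str = ""
    bam: str = ""
    reference_bam: str = ""
    reference_fasta: str = ""  # required for CRAM
    family_tsv: str = ""
    genome_build: str = "hg38"  # metadata only; no liftover
    # outputs
    out_dir: str = "cnvtriage_out"
    output_formats: list[str] = field(default_factory=lambda: ["tsv", "json", "txt"])
    interpretations_file: str = ""
    plot_dir: str = ""
    # pre-processing / filtration
    premerge: bool = True
    merge_max_gap: int = 50_000
    skip_filtration: bool = False
    af_threshold: float = DEFAULT_AF_THRESHOLD
    problem_region_union: bool = True
    # scoring
    pli_cutoff: float = 0.9
    adverse_reciprocal_overlap: float = 0.7
    adverse_popmax_af: float = 0.01
    deletion_ratio_max: float = 0.85
    duplication_ratio_min: float = 1.15
    min_median_mq: float = 20.0
    problem_fraction_max: float = 0.7
    # evidence
    n_bins: int = DEFAULT_N_BINS
    insert_lower_pct: float = DEFAULT_LOWER_PCT
    insert_upper_pct: float = DEFAULT_UPPER_PCT
    breakpoint_tolerance: int = DEFAULT_BREAKPOINT_TOLERANCE
    reference_deviation_threshold: float = 0.3
    # inheritance
    min_reciprocal_inheritance: float = DEFAULT_MIN_RECIPROCAL

    def __post_init__(self):
        if self.genome_build not in GENOME_BUILDS:
            raise ValueError(f"genome_build must be one of {GENOME_BUILDS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def score_config(self) -> ScoreConfig:
        return ScoreConfig(
            pli_cutoff=self.pli_cutoff,
            adverse_reciprocal_overlap=self.adverse_reciprocal_overlap,
            adverse_popmax_af=self.adverse_popmax_af,
            deletion_ratio_max=self.deletion_ratio_max,
            duplication_ratio_min=self.duplication_ratio_min,
            min_median_mq=self.min_median_mq,
            problem_fraction_max=self.problem_fraction_max,
        )

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


CONFIG_TEMPLATE = """\
# cnvtriage run configuration (flat key: value; unknown keys are rejected)
cnv_path: calls.tsv          # CNV list (bed_tsv: chrom  start  end  type)
cnv_dialect: bed_tsv         # bed_tsv | vcf
sample_id: SAMPLE
family_id: ""                # enables inheritance labelling when family data present
annodir: annotations/        # directory of annotation tables
bam: ""                      # proband BAM/CRAM (indexed); empty = annotation-only
reference_bam: ""            # control sample overlay (e.g. NA12878)
reference_fasta: ""          # needed for CRAM decoding
family_tsv: ""               # extra family CNVs: sample_id family_id relation chrom start end type
genome_build: hg38           # hg19 | hg38 (metadata only)
out_dir: cnvtriage_out
output_formats: [tsv, json, txt]
interpretations_file: ""     # central interpretation store (text)
plot_dir: ""                 # emit static evidence plots here
premerge: true               # merge fragmented same-type calls before filtration
merge_max_gap: 50000         # bp
skip_filtration: false       # jump straight to prioritization
af_threshold: 0.01           # population containment removal above this AF
problem_region_union: true   # containment vs merged union of problem regions
pli_cutoff: 0.9
adverse_reciprocal_overlap: 0.7
adverse_popmax_af: 0.01
deletion_ratio_max: 0.85     # depth ratio above this contradicts a deletion
duplication_ratio_min: 1.15  # depth ratio below this contradicts a duplication
min_median_mq: 20.0
problem_fraction_max: 0.7
n_bins: 200
insert_lower_pct: 0.5
insert_upper_pct: 99.5
breakpoint_tolerance: 1000   # bp, for supporting-read counting
reference_deviation_threshold: 0.3
min_reciprocal_inheritance: 0.5
"""
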