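"""Pipeline-wide configuration: every numeric threshold in one place.

Defaults reflect the standard small-RNA curation practice this package
implements: Illumina TruSeq-style 3' adapter, 18-25 nt mature-length window,
five hairpin curation criteria, 1e-5 alignment E-value significance, >5-locus
repetitive cutoff, 10 kb cluster gap, DESeq2-style differential-expression
thresholds, the reference-gene prescreen window, and the Cq = 30 ceiling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

#: 3' sequencing adapter ligated to every small-RNA insert.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline with their defaults."""

    # preprocessing
    adapter: str = DEFAULT_ADAPTER
    min_insert_len: int = 18
    max_insert_len: int = 25
    adapter_min_overlap: int = 8
    adapter_max_mismatch_rate: float = 0.125  # <=1 mismatch per 8 nt

    # discovery / curation
    min_stack_reads: int = 5
    stack_gap: int = 25
    excision_flank: int = 70
    max_read_loci: int = 5          # reads at more loci are multi-locus
    min_samples_detected: int = 2   # criterion 1
    min_arm_reads: int = 10         # criterion 2, summed across samples
    overhang_min: int = 0           # criterion 3
    overhang_max: int = 4
    homogeneity_fraction: float = 0.5   # criterion 4, strictly greater
    pairing_fraction: float = 0.60      # criterion 5, strictly greater

    # annotation
    evalue_threshold: float = 1e-5
    repetitive_locus_cutoff: int = 5    # >5 genomic loci => repetitive
    species_prefix: str = "slu"
    passenger_ratio: float = 10.0       # guide/passenger >= 10 => passenger
    # local-alignment scoring (megablast-like) and Karlin-Altschul constants
    match_score: int = 5
    mismatch_score: int = -4
    gap_open_score: int = -8
    gap_extend_score: int = -2
    ka_lambda: float = 0.27
    ka_k: float = 0.28

    # clusters
    cluster_max_gap: int = 10_000

    # quantification
    count_max_mismatches: int = 1
    count_max_offset5: int = 2
    count_max_offset3: int = 5
    diversity_threshold: float = 0.0

    # differential expression
    de_min_normalized: float = 30.0
    de_min_abs_lfc: float = 1.0
    de_max_padj: float = 0.05
    de_pseudocount: float = 0.5
    dispersion_floor: float = 1e-8

    # reference-gene stability prescreen
    prescreen_low: float = 2_500.0
    prescreen_high: float = 130_000.0
    prescreen_max_rsd: float = 0.3

    # qPCR
    cq_cutoff: float = 30.0
    default_efficiency: float = 2.0

    seed: int = 42

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(s))

    def hash(self) -> str:
        """Short stable digest of the serialized config, stamped on outputs."""
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]
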