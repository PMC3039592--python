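"""Run configuration: every tunable threshold in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .simulate import DEPTH_LOG_MEDIAN, DEPTH_LOG_SIGMA

#: Clock rates (substitutions/site/year) under the three commonly used
#: divergence-time calibrations for the taurine/bison split.
CALIBRATIONS = {
    "1MY": (1.0e6, 3.3e-8),
    "2MY": (2.0e6, 1.6e-8),
    "5MY": (5.0e6, 6.6e-9),
}


@dataclass
class RunConfig:
    seed: int = 0
    # consensus thresholds
    min_depth: int = 1
    low_coverage_threshold: int = 10  # amplicons below this get re-pooled
    min_identity: float = 0.7
    primer_mismatches: int = 1
    # authentication thresholds
    run_threshold: int = 5  # homopolymer length above which indels are artifacts
    maf_threshold: float = 0.02
    support_threshold: float = 0.75
    # dating
    calibration: str = "1MY"
    generation_time: float = 7.0
    # simulation geometry
    genome_length: int = 16338
    n_amplicons: int = 130
    n_sets: int = 4
    insert_min: int = 155
    insert_max: int = 230
    min_overlap: int = 30
    # simulated truth
    n_substitutions: int = 7
    n_indels: int = 1
    damage_rate: float = 0.004
    seq_error_rate: float = 0.01
    homopolymer_indel_base_rate: float = 0.03
    contamination_fraction: float = 0.0
    depth_log_median: float = DEPTH_LOG_MEDIAN
    depth_log_sigma: float = DEPTH_LOG_SIGMA
    modern_panel_size: int = 10
    modern_panel_substitutions: float = 8.0  # Poisson mean per genome
    replicate_amplicons: int = 16  # amplicons re-simulated for concordance
    # output
    write_reads: bool = False
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.low_coverage_threshold < 1:
            raise ValueError("low_coverage_threshold must be >= 1")
        if not 0.5 < self.support_threshold <= 1.0:
            raise ValueError("support_threshold must be in (0.5, 1]")
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")
        if self.run_threshold < 1:
            raise ValueError("run_threshold must be >= 1")
        if self.calibration not in CALIBRATIONS:
            raise ValueError(f"calibration must be one of {sorted(CALIBRATIONS)}")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be > 0")
        if self.primer_mismatches < 0:
            raise ValueError("primer_mismatches must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
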