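"""Pipeline configuration and stage orchestration behind the CLI.

Every threshold the stages use lives in :class:`PipelineConfig` with the
published defaults (mapping: >= 8 matching bases at >= 70% identity; read
QC: >= 50 nt and < 60% single-nucleotide content; gene-evidence identity
>= 90%).  The config hashes stably so every run can log which parameter
set produced its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for a pipeline run."""

    genome: Optional[str] = None
    annotation: Optional[str] = None
    annotation_dialect: str = "table2_tsv"
    reads: Optional[str] = None
    outdir: str = "."

    k: int = 11
    min_match_bases: int = 8
    min_match_pct: float = 0.70
    min_identity: float = 0.90
    read_min_len: int = 50
    homopolymer_frac: float = 0.60
    polyA_min: int = 5
    band_frac: float = 0.15

    punctuation_rule: str = "all"
    library_total_reads: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("min_match_pct", 0.0, 1.0),
            ("min_identity", 0.0, 1.0),
            ("homopolymer_frac", 0.0, 1.0),
            ("band_frac", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.k < 4 or self.min_match_bases < 1 or self.read_min_len < 1:
            raise ValueError("k, min_match_bases and read_min_len must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
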