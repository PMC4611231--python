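"""Pipeline configuration.

Defaults reproduce the study settings: rarefaction to 6871 sequences per
sample, de-novo OTUs at 97% identity, 33-nt V4 ribotags, Q20 truncation with
>75 bp retention and fewer than 3 low-quality bases, the 1000 x 10000
resampling test at a 98% confidence threshold, and the viral-quotient filter
(VQ > 0.8, >= 1000 total counts).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    rarefaction_depth: int = 6871
    otu_identity: float = 0.97
    tag_length: int = 33
    qc_min_length: int = 75
    qc_trunc_phred: int = 20
    qc_max_lowq: int = 3
    resample_n: int = 1000
    resample_size: int = 10000
    resample_conf: float = 0.98
    vq_min: float = 0.8
    vq_min_counts: int = 1000
    pssm_threshold_frac: float = 0.8
    lca_score_margin: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValidationError("rarefaction_depth must be >= 1")
        if not 0 < self.otu_identity <= 1:
            raise ValidationError("otu_identity must lie in (0, 1]")
        if self.tag_length < 1:
            raise ValidationError("tag_length must be >= 1")
        if self.qc_trunc_phred < 0 or self.qc_max_lowq < 0:
            raise ValidationError("QC thresholds must be non-negative")
        if self.resample_n < 1 or self.resample_size < 1:
            raise ValidationError("resampling sizes must be >= 1")
        if not 0 < self.resample_conf < 1:
            raise ValidationError("resample_conf must lie in (0, 1)")
        if not 0 <= self.vq_min <= 1:
            raise ValidationError("vq_min must lie in [0, 1]")
        if not 0 < self.pssm_threshold_frac <= 1:
            raise ValidationError("pssm_threshold_frac must lie in (0, 1]")
        if not 0 <= self.lca_score_margin <= 1:
            raise ValidationError("lca_score_margin must lie in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a JSON or YAML mapping of field names to values."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
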