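"""Pipeline configuration: every numeric default is the value used throughout
the method description (head/tail lengths, decoys per site, filter windows,
the informative-read model constants)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field


class PipelineConfig(BaseModel):
    mode: Literal["intronic", "distal"] = "intronic"
    seed: int = 0

    head_len: int = Field(20, gt=0)
    tail_len: int = Field(250, gt=0)
    decoys_per_site: int = Field(5, ge=0)
    include_site_pairs: bool = True

    max_ambiguous_frac: float = Field(0.05, ge=0, le=1)
    linear_mismatch_rate: float = Field(0.0133, ge=0, le=1)

    min_prefix: int = Field(20, gt=0)
    proximity_window: int = Field(100, ge=0)
    bp_dist_min: int = Field(10, ge=0)
    bp_dist_max: int = Field(60, ge=0)
    mismatch_fraction: float = Field(0.05, ge=0, le=1)
    selfprime_k: int = Field(5, gt=0)
    disabled_filters: list[str] = Field(default_factory=list)

    mc_samples: int = Field(1000, gt=0)
    bp_offset: int = Field(25, gt=0)
    read_len_grid: list[int] = Field(default_factory=lambda: [75, 100, 150])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
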