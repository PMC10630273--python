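"""Run configuration: every tunable threshold of the pipeline in one
place, with YAML round-trip, strict unknown-key rejection and a stable
content hash for run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    # cassette mining
    max_gap_genes: int = 2
    all_cassettes: bool = False
    # shuffling thresholds
    high_id: float = 0.9
    low_id: float = 0.5
    endolysin_cluster_id: float = 0.9
    ucwb_cluster_id: float = 0.8
    # segmentation / linker
    min_ucwb_len: int = 40
    linker_min_len: int = 12
    linker_max_len: int = 16
    linker_search_span: int = 80
    linker_pk_threshold: float = 0.5
    linker_motif_tolerance: int = 3
    # I/O
    vocab_path: str | None = None
    histogram_bin_bp: int = 5_000

    def __post_init__(self) -> None:
        checks = [
            (self.max_gap_genes >= 0, "max_gap_genes must be >= 0"),
            (0.0 <= self.low_id <= self.high_id <= 1.0,
             "need 0 <= low_id <= high_id <= 1"),
            (0.0 < self.endolysin_cluster_id <= 1.0,
             "endolysin_cluster_id must be in (0, 1]"),
            (0.0 < self.ucwb_cluster_id <= 1.0,
             "ucwb_cluster_id must be in (0, 1]"),
            (self.min_ucwb_len > 0, "min_ucwb_len must be positive"),
            (0 < self.linker_min_len <= self.linker_max_len,
             "need 0 < linker_min_len <= linker_max_len"),
            (self.linker_search_span > 0, "linker_search_span must be positive"),
            (0.0 < self.linker_pk_threshold <= 1.0,
             "linker_pk_threshold must be in (0, 1]"),
            (self.linker_motif_tolerance >= 0,
             "linker_motif_tolerance must be >= 0"),
            (self.histogram_bin_bp > 0, "histogram_bin_bp must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def to_dict(self) -> dict[str, object]:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def linker_kwargs(self) -> dict[str, object]:
        return {
            "min_len": self.linker_min_len,
            "max_len": self.linker_max_len,
            "search_span": self.linker_search_span,
            "pk_threshold": self.linker_pk_threshold,
            "motif_tolerance": self.linker_motif_tolerance,
        }
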