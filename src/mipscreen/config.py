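"""Pipeline configuration: every tunable threshold in one place.

The serialized configuration (and a short hash of it) is embedded in the
header of every output file so results are traceable to the exact
thresholds that produced them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    max_maf: float = 0.01
    min_rf: float = 0.15
    del_thresh: float = 0.7
    dup_thresh: float = 1.3
    min_run: int = 7
    spliceai_delta: float = 0.2
    spliceai_hits: int = 2
    missense_min_criteria: int = 4
    manual_cov: int = 10
    sanger_cov: int = 5
    median_floor: int = 20
    percent_convention: str = "round"  # round (half-up) | truncate
    mean_depth: float = 1488.0
    dispersion: float = 150.0
    efficiency_sigma: float = 1.0
    benign_fraction: float = 1.0
    seed: int = 0

    _RANGES = {
        "max_maf": (0.0, 1.0), "min_rf": (0.0, 1.0), "del_thresh": (0.0, 1.0),
        "dup_thresh": (1.0, 10.0), "min_run": (2, 1000),
        "spliceai_delta": (0.0, 1.0), "spliceai_hits": (1, 4),
        "missense_min_criteria": (0, 5), "manual_cov": (0, 10_000),
        "sanger_cov": (0, 10_000), "median_floor": (0, 10_000),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside its range [{lo}, {hi}]")
        if self.sanger_cov > self.manual_cov:
            raise ValueError("sanger_cov cannot exceed manual_cov")
        if self.percent_convention not in ("round", "truncate"):
            raise ValueError("percent_convention must be 'round' or 'truncate'")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def header_line(self) -> str:
        return f"#mipscreen config_hash={self.hash}"
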