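"""Pipeline configuration: every analysis constant, with study defaults.

Defaults are the constants the analysis is defined with — a 0.765 IoU
consensus threshold, 60 s TSO agreement tolerance, <3 s bout gap merging,
>=2 s minimum bout duration, <30 min sleep-period merging, <3.5 h short-TSO
exclusion, 10 s epochs (1 s sensitivity variant), log offset 1, 500
bootstrap resamples.  All are overridable from YAML/JSON and round-trip
losslessly through the provenance record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

__all__ = ["PipelineConfig"]


def _default_itch_bands() -> list:
    return [["no itch", 0, 0], ["mild", 1, 3], ["moderate", 4, 6], ["severe", 7, 10]]


@dataclass
class PipelineConfig:
    events_csv: Optional[str] = None
    pro_csv: Optional[str] = None
    participants_csv: Optional[str] = None
    out_dir: str = "nightscratch_out"
    epoch_s: float = 10.0
    sensitivity_epoch_s: Optional[float] = None  # e.g. 1.0 for the sensitivity analysis
    merge_gap_s: float = 3.0
    min_bout_s: float = 2.0
    tso_merge_gap_min: float = 30.0
    tso_min_hours: float = 3.5
    iou_threshold: float = 0.765
    tso_tolerance_s: float = 60.0
    log_offset: float = 1.0
    bootstrap_n: int = 500
    seed: int = 0
    itch_bands: list = field(default_factory=_default_itch_bands)
    pro_window_start: str = "04:00"
    pro_window_end: str = "12:00"

    def __post_init__(self) -> None:
        for name in ("epoch_s", "merge_gap_s", "min_bout_s", "tso_merge_gap_min",
                     "tso_min_hours", "tso_tolerance_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.iou_threshold <= 1.0:
            raise ValueError("iou_threshold must be in [0, 1]")
        if self.bootstrap_n < 1:
            raise ValueError("bootstrap_n must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def write_provenance(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
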