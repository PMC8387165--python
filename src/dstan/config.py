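"""Run configuration: one YAML file binding the whole pipeline.

Defaults reproduce the reference settings: sequences normalised to t=9
frames at 224x224, channel-attention compression ratio r=16, Adam on
cross-entropy with batch size 32; a single master seed funnels every source
of randomness.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from dstan.streams import StreamConfig


@dataclass
class RunConfig:
    data_root: str = "data"
    labels_file: str = "data/labels.csv"
    output_dir: str = "runs/out"
    t: int = 9
    frame_size: int = 224
    flow_estimator: str = "ilk"
    fusion: str = "svm"          # svm | average | both
    seed: int = 0
    log_level: str = "INFO"
    stan: StreamConfig = field(default_factory=lambda: StreamConfig(input_channels=1))
    stmn: StreamConfig = field(default_factory=lambda: StreamConfig(input_channels=2))

    def __post_init__(self) -> None:
        size = (self.frame_size, self.frame_size)
        for cfg in (self.stan, self.stmn):
            cfg.frame_size = size
            cfg.t = self.t
            cfg.seed = self.seed

    @property
    def fusion_kinds(self) -> tuple[str, ...]:
        return ("svm", "average") if self.fusion == "both" else (self.fusion,)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        stan = StreamConfig(**raw.pop("stan", {})) if not isinstance(
            raw.get("stan"), StreamConfig) else raw.pop("stan")
        stmn_raw = raw.pop("stmn", {"input_channels": 2})
        stmn = StreamConfig(**stmn_raw) if not isinstance(stmn_raw, StreamConfig) else stmn_raw
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(stan=stan, stmn=stmn, **known)
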