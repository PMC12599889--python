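"""Run configuration: one plain-text (YAML) file drives the whole pipeline.

Defaults reproduce the study protocol constants: 66 participants, 9
perturbations per trial, 3 perturbation trials, 2 s windows, 10 splits at
70/15/15.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import yaml

from ..detector import ModelConfig
from ..experiments import DEFAULT_CONDITIONS, Condition
from ..windowing import WindowingConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one full experiment run."""

    n_participants: int = 66
    seed: int = 0
    amplitude_ratio: float = 4.0
    gait_duration: float = 60.0
    n_splits: int = 10
    fractions: Tuple[float, float, float] = (0.70, 0.15, 0.15)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    conditions: Optional[List[dict]] = None  # None -> the default 14
    output_dir: str = "runs/default"
    verbosity: str = "INFO"

    def condition_objects(self) -> List[Condition]:
        if self.conditions is None:
            return list(DEFAULT_CONDITIONS)
        return [
            Condition(
                name=c["name"],
                positions=tuple(c["positions"]),
                channel_set=c.get("channel_set", "accel_gyro"),
            )
            for c in self.conditions
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "windowing" in raw and isinstance(raw["windowing"], dict):
            raw["windowing"] = WindowingConfig(**raw["windowing"])
        if "model" in raw and isinstance(raw["model"], dict):
            raw["model"] = ModelConfig(**raw["model"])
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance stamps."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
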