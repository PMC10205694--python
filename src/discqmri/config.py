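"""Run configuration: one structured record serialised with every output.

All defaults mirror the pipeline's documented analysis choices (TSL grid,
clamp, noise threshold, NP fraction, minimum voxel count, model coding).
The config hash recorded in artifacts makes reruns auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .relaxometry import DEFAULT_TSL_MS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    tsl_ms: tuple = DEFAULT_TSL_MS
    noise_sigma: float = 1.0
    noise_k: float = 3.0
    t_min: float = 1.0
    t_max: float = 500.0
    np_fraction: float = 0.40
    min_voxels: int = 10
    axis_convention: dict = dataclasses.field(
        default_factory=lambda: {"slice": "LR", "row": "SI", "col": "AP"}
    )
    age_center: float | None = None  # None -> sample mean
    seed: int = 20230101
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.np_fraction <= 1:
            raise ValueError("np_fraction must lie in (0, 1]")
        if not 0 < self.t_min < self.t_max:
            raise ValueError("clamp bounds must be ordered")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tsl_ms"] = [float(t) for t in self.tsl_ms]
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "tsl_ms" in raw:
            raw["tsl_ms"] = tuple(raw["tsl_ms"])
        return cls(**raw)

    def fit_config(self):
        from .relaxometry import FitConfig

        return FitConfig(
            t_min=self.t_min,
            t_max=self.t_max,
            noise_sigma=self.noise_sigma,
            noise_k=self.noise_k,
        )
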