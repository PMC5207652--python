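"""Run configuration: YAML-serializable settings for every stage."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import BODY_THRESHOLD_HU, FatWindow
from .synthetic import PhantomParams


@dataclass
class RunConfig:
    seed: int = 0
    cohort: dict = field(default_factory=dict)   # PhantomParams overrides
    window_lower: float = -170.0
    window_upper: float = -40.0
    opening_radius: int = 1
    body_threshold_hu: float = BODY_THRESHOLD_HU
    n_calibration: int = 20
    with_scc: bool = True
    welch: bool = False
    with_peripheral_slices: bool = True

    def phantom_params(self) -> PhantomParams:
        kw = dict(self.cohort)
        kw.setdefault("seed", self.seed)
        for key in ("grid_shape", "spacing", "landmark_labels", "body_radii_mm"):
            if key in kw and isinstance(kw[key], list):
                kw[key] = tuple(kw[key])
        return PhantomParams(**kw)

    def fat_window(self) -> FatWindow:
        return FatWindow(self.window_lower, self.window_upper)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()
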