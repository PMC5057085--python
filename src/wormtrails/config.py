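"""Pipeline configuration: one object holding every tunable, with the
standard defaults (50-frame/50-px gap caps, 100-px overlap margin, 1-s
prune, 3-s consolidate, 50-px body length).

Precedence is CLI flags > config file > defaults; unknown keys in a config
file are rejected rather than ignored so typos cannot silently change a
run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["Config", "load_config"]


@dataclass
class Config:
    # simulation
    preset: str = "default"
    seed: int = 0
    n_worms: int = 10
    duration_s: float = 120.0
    fps: float = 5.0
    body_length_px: float = 50.0
    # correction pipeline
    max_gap_frames: int = 50
    max_gap_px: float = 50.0
    overlap_threshold: float = 100.0
    prune_max_s: float = 1.0
    consolidate_max_s: float = 3.0
    max_passes: int = 10
    # coverage / motility
    coverage_thresholds: tuple = (0.5, 0.9, 0.99)
    short_trail_s: float = 60.0
    interp_max_gap_s: float = 1.0
    pos_window_s: float = 1.0
    speed_window_s: float = 60.0
    bin_s: float = 60.0
    windows_min: tuple = ((0.0, 30.0), (30.0, 90.0), (90.0, 180.0))
    active_min_threshold: float = 5.0
    active_speed_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.max_gap_frames <= 0 or self.max_gap_px <= 0:
            raise ValueError("gap caps must be positive")
        if self.overlap_threshold < 0:
            raise ValueError("overlap_threshold must be non-negative")
        if self.prune_max_s <= 0 or self.consolidate_max_s <= 0:
            raise ValueError("prune/consolidate spans must be positive")
        if self.body_length_px <= 0:
            raise ValueError("body_length_px must be positive")
        if self.max_passes < 1:
            raise ValueError("max_passes must be at least 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coverage_thresholds"] = list(self.coverage_thresholds)
        d["windows_min"] = [list(w) for w in self.windows_min]
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def provenance(self) -> dict:
        from . import __version__
        return {"config_sha256": self.digest(), "seed": self.seed,
                "version": __version__}


_FIELDS = {f.name for f in dataclasses.fields(Config)}


def load_config(path=None, **overrides) -> Config:
    """Build a Config from an optional YAML file plus keyword overrides.

    Unknown keys anywhere are an error.  Overrides with value None are
    treated as "not given".
    """
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(loaded) - _FIELDS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update(loaded)
    for k, v in overrides.items():
        if k not in _FIELDS:
            raise ValueError(f"unknown config key: {k}")
        if v is not None:
            data[k] = v
    if "windows_min" in data:
        data["windows_min"] = tuple(tuple(w) for w in data["windows_min"])
    if "coverage_thresholds" in data:
        data["coverage_thresholds"] = tuple(data["coverage_thresholds"])
    return Config(**data)
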