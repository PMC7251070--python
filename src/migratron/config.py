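"""Run configuration: YAML in, resolved YAML out next to the results.

Every run writes its fully resolved parameter set to the output directory so
any result can be reproduced from config + inputs alone.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .pipeline import DetectParams
from .preprocess import PreprocessParams


@dataclass
class SliceInput:
    slice_id: str
    stack: str
    rois: str


@dataclass
class RunConfig:
    slices: list[SliceInput] = field(default_factory=list)
    channel_map: dict[int, str] = field(default_factory=lambda: {0: "green", 1: "red"})
    pixel_size_um: float | None = None  # None → take from TIFF metadata
    z_step_um: float | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detect: DetectParams = field(default_factory=DetectParams)
    n_bins: int = 10
    migration_metric: str = "dist_cp"  # or "dist_vent"
    cp_roi_name: str = "cp_top"
    vent_roi_name: str = "ventricle"
    output_dir: str = "migratron_out"
    brain_id: str = ""
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.migration_metric not in ("dist_cp", "dist_vent"):
            raise ValueError("migration_metric must be 'dist_cp' or 'dist_vent'")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    slices = [SliceInput(**s) for s in raw.pop("slices", [])]
    pre = PreprocessParams(**raw.pop("preprocess", {}))
    det = DetectParams(**raw.pop("detect", {}))
    channel_map = {int(k): v for k, v in raw.pop("channel_map", {0: "green", 1: "red"}).items()}
    return RunConfig(slices=slices, channel_map=channel_map, preprocess=pre, detect=det, **raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
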