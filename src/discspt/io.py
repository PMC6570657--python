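"""File formats, configuration and run manifests.

Trajectory interchange is a CSV with header ``track_id,frame,x_um,y_um[,state]``,
one row per localization, frames 0-based and consecutive within a track.
Movies are multi-page 16-bit grayscale TIFF; configuration is YAML;
reports are JSON with unit-suffixed keys.
"""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .movie import MovieStack
from .trajectories import TrajectorySet

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_movie",
    "write_movie",
    "load_config",
    "RunManifest",
]

_REQUIRED_COLS = ("track_id", "frame", "x_um", "y_um")


def read_trajectories(path) -> TrajectorySet:
    """Read a trajectory CSV, validating structure row by row.

    Raises ``ValueError`` naming offending line numbers for missing columns,
    non-numeric coordinates, duplicate (track, frame) pairs or
    non-consecutive frames.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty and df.columns.size == 0:
        raise ValueError(f"{path}: empty file")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("x_um", "y_um"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]
            raise ValueError(f"{path}: non-numeric {col} at lines {lines}")
        df[col] = pd.to_numeric(df[col])
    if df[["track_id", "frame"]].duplicated().any():
        dup = df[df[["track_id", "frame"]].duplicated()]
        lines = (dup.index + 2).tolist()[:5]
        raise ValueError(f"{path}: duplicate (track_id, frame) pairs at lines {lines}")
    if df.empty:
        raise ValueError(f"{path}: no trajectory rows")
    for tid, sub in df.groupby("track_id"):
        frames = np.sort(sub["frame"].to_numpy())
        if not np.all(np.diff(frames) == 1):
            raise ValueError(f"{path}: track {tid} has non-consecutive frames")
    return TrajectorySet.from_frame(df)


def write_trajectories(trajset: TrajectorySet, path, include_state: bool = True) -> None:
    """Write a trajectory set to CSV (roundtrips with read_trajectories)."""
    df = trajset.to_frame(include_state=include_state)
    # %.17g guarantees exact float64 roundtrip through text
    df.to_csv(path, index=False, float_format="%.17g")


def read_movie(path, pixel_size: float = 0.076, frame_interval: float = 1.0 / 30.0) -> MovieStack:
    """Read a multi-page TIFF as a MovieStack (metadata from arguments)."""
    data = tifffile.imread(path)
    return MovieStack(np.asarray(data), pixel_size=pixel_size, frame_interval=frame_interval)


def write_movie(movie: MovieStack, path) -> None:
    tifffile.imwrite(path, movie.data.astype(np.uint16), photometric="minisblack")


def load_config(path) -> dict:
    """Load a YAML configuration file into a nested dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


@dataclass
class RunManifest:
    """Record sufficient to reproduce a run bit-identically: the command,
    the configuration snapshot, the master seed, software versions and the
    input/output paths."""

    command: str
    config: dict
    seed: int
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        from . import __version__

        return {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "inputs": [str(p) for p in self.inputs],
            "outputs": [str(p) for p in self.outputs],
            "versions": {
                "discspt": __version__,
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "platform": platform.platform(),
            },
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
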