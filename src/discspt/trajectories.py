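"""Trajectory containers.

A :class:`Trajectory` is a time-ordered sequence of 2-D localizations of one
particle; a :class:`TrajectorySet` is an ordered collection of them.
Simulated trajectories may carry hidden ground-truth state labels (one per
displacement step) and, after localization noise has been applied, the
noise-free positions — both are used only by oracle tests, never by
inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "TrajectorySet"]


@dataclass
class Trajectory:
    """One particle track: consecutive frames and positions in µm."""

    track_id: int
    frames: np.ndarray
    positions: np.ndarray
    true_states: np.ndarray | None = None
    true_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n_frames, 2)")
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions must have equal length")
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not np.all(np.diff(self.frames) == 1):
            raise ValueError("frames must increase consecutively by 1")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.true_states is not None:
            self.true_states = np.asarray(self.true_states, dtype=np.int64)
            if len(self.true_states) != len(self.frames) - 1:
                raise ValueError("true_states needs one entry per displacement step")
        if self.true_positions is not None:
            self.true_positions = np.asarray(self.true_positions, dtype=float)
            if self.true_positions.shape != self.positions.shape:
                raise ValueError("true_positions must match positions in shape")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        return len(self.frames) - 1

    def steps(self) -> np.ndarray:
        """Displacement vectors between consecutive frames, shape (n_steps, 2)."""
        return np.diff(self.positions, axis=0)


@dataclass
class TrajectorySet:
    """Ordered collection of trajectories from one condition/run."""

    trajectories: list[Trajectory] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    @property
    def n_steps(self) -> int:
        return sum(t.n_steps for t in self.trajectories)

    def lengths(self) -> np.ndarray:
        return np.array([len(t) for t in self.trajectories], dtype=np.int64)

    def to_frame(self, include_state: bool = True) -> pd.DataFrame:
        """Long-format table: ``track_id, frame, x_um, y_um[, state]``.

        Per-step state labels are attached to the row of the step's first
        frame; the final frame of each track carries the last step's label.
        """
        records = []
        for t in self.trajectories:
            df = pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": t.frames,
                    "x_um": t.positions[:, 0],
                    "y_um": t.positions[:, 1],
                }
            )
            if include_state and t.true_states is not None:
                state = np.empty(len(t), dtype=np.int64)
                state[:-1] = t.true_states
                state[-1] = t.true_states[-1]
                df["state"] = state
            records.append(df)
        if not records:
            return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
        return pd.concat(records, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrajectorySet":
        """Build a set from a long-format table (inverse of :meth:`to_frame`)."""
        trajs = []
        for tid, sub in df.groupby("track_id", sort=True):
            sub = sub.sort_values("frame")
            states = None
            if "state" in sub.columns and sub["state"].notna().all():
                states = sub["state"].to_numpy(dtype=np.int64)[:-1]
            trajs.append(
                Trajectory(
                    track_id=int(tid),
                    frames=sub["frame"].to_numpy(),
                    positions=sub[["x_um", "y_um"]].to_numpy(dtype=float),
                    true_states=states,
                )
            )
        return cls(trajs)
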