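"""Tracked planar trajectories for one climbing trial.

A :class:`TrajectorySet` holds per-fly, per-frame (x, y) positions in
millimetres for a single startle-induced climbing trial, together with the
arena geometry and frame rate.  The on-disk interchange format is the
tracker-output table shape: a CSV with columns ``frame, fly_id, x_mm, y_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

DEFAULT_FPS = 60.0
DEFAULT_DURATION_FRAMES = 601
DEFAULT_ARENA_WIDTH_MM = 28.0
DEFAULT_ARENA_HEIGHT_MM = 90.0


@dataclass
class TrajectorySet:
    """Per-fly, per-frame positions for one trial.

    Parameters
    ----------
    positions
        Array of shape ``(n_flies, n_frames, 2)`` holding (x, y) in mm.
    fps
        Frames per second (default 60).
    arena_width, arena_height
        Arena dimensions in mm (default 28 x 90).
    trial_id, group
        Free-form identifiers carried through the pipeline.
    """

    positions: np.ndarray
    fps: float = DEFAULT_FPS
    arena_width: float = DEFAULT_ARENA_WIDTH_MM
    arena_height: float = DEFAULT_ARENA_HEIGHT_MM
    trial_id: str = "trial0"
    group: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise InvalidInputError(
                f"positions must have shape (n_flies, n_frames, 2), "
                f"got {self.positions.shape}"
            )
        if self.fps <= 0:
            raise InvalidInputError("fps must be positive")
        if self.arena_width <= 0 or self.arena_height <= 0:
            raise InvalidInputError("arena dimensions must be positive")
        x = self.positions[..., 0]
        y = self.positions[..., 1]
        eps = 1e-9
        if np.any(x < -eps) or np.any(x > self.arena_width + eps):
            raise InvalidInputError("x positions outside [0, arena_width]")
        if np.any(y < -eps) or np.any(y > self.arena_height + eps):
            raise InvalidInputError("y positions outside [0, arena_height]")

    @property
    def n_flies(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_frames(self) -> int:
        return self.positions.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns frame, fly_id, x_mm, y_mm."""
        n_flies, n_frames, _ = self.positions.shape
        frames = np.tile(np.arange(n_frames), n_flies)
        fly_ids = np.repeat(np.arange(n_flies), n_frames)
        flat = self.positions.reshape(-1, 2)
        return pd.DataFrame(
            {
                "frame": frames,
                "fly_id": fly_ids,
                "x_mm": flat[:, 0],
                "y_mm": flat[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        fps: float = DEFAULT_FPS,
        arena_width: float = DEFAULT_ARENA_WIDTH_MM,
        arena_height: float = DEFAULT_ARENA_HEIGHT_MM,
        trial_id: str = "trial0",
        group: str = "",
    ) -> "TrajectorySet":
        required = {"frame", "fly_id", "x_mm", "y_mm"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"trajectory table missing columns: {sorted(missing)}")
        fly_ids = np.sort(df["fly_id"].unique())
        frames = np.sort(df["frame"].unique())
        n_flies, n_frames = len(fly_ids), len(frames)
        if len(df) != n_flies * n_frames:
            raise InvalidInputError(
                "trajectory table is not a complete (fly, frame) grid"
            )
        wide = df.sort_values(["fly_id", "frame"])
        positions = wide[["x_mm", "y_mm"]].to_numpy(dtype=float).reshape(
            n_flies, n_frames, 2
        )
        return cls(
            positions=positions,
            fps=fps,
            arena_width=arena_width,
            arena_height=arena_height,
            trial_id=trial_id,
            group=group,
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TrajectorySet":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)
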