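"""Per-fly, per-frame speed and heading from tracked coordinates.

Speed at frame i is the displacement from frame i-1 times the frame rate
(mm/s).  Heading is the displacement direction in degrees with 0 deg =
straight up, +90 deg = rightward, -90 deg = leftward, range (-180, 180];
frames whose displacement is below ``min_disp`` get an undefined (NaN)
heading and are excluded from angular statistics.  Movement outside
(-30 deg, +30 deg) of vertical counts as abnormal directional movement;
fractions are reported per second and accumulated over the analysis
window (first 3 s by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidInputError, UndefinedStatisticError
from .trajectory import TrajectorySet

__all__ = [
    "AbnormalDirectionResult",
    "DEFAULT_MIN_DISP_MM",
    "Histogram",
    "abnormal_direction_fraction",
    "angular_histogram",
    "compute_kinematics",
    "heading_angle",
    "instantaneous_speed",
    "speed_histogram",
]

DEFAULT_MIN_DISP_MM = 0.02  # 1.2 mm/s at 60 fps: jitter floor for stationary flies


def compute_kinematics(
    traj: TrajectorySet, min_disp: float = DEFAULT_MIN_DISP_MM
) -> pd.DataFrame:
    """Per-frame speed and heading for every fly.

    Returns a table with columns ``fly_id, frame, speed_mm_s, heading_deg``;
    frame 0 has no displacement and is omitted.  ``heading_deg`` is NaN
    where the displacement norm is below ``min_disp``.
    """
    if min_disp < 0:
        raise InvalidArgumentError("min_disp must be >= 0")
    if traj.duration_frames < 2:
        raise InvalidInputError("need at least 2 frames to compute kinematics")
    disp = np.diff(traj.positions, axis=1)  # (n_flies, n_frames-1, 2)
    norms = np.linalg.norm(disp, axis=2)
    speed = norms * traj.fps
    # atan2(dx, dy): 0 deg points up, positive clockwise (to the right)
    heading = np.degrees(np.arctan2(disp[..., 0], disp[..., 1]))
    heading = np.where(norms >= max(min_disp, 1e-300), heading, np.nan)
    # atan2 returns -180 for straight-down; map into (-180, 180]
    heading = np.where(heading == -180.0, 180.0, heading)

    n_flies, n_steps = speed.shape
    return pd.DataFrame(
        {
            "fly_id": np.repeat(np.arange(n_flies), n_steps),
            "frame": np.tile(np.arange(1, n_steps + 1), n_flies),
            "speed_mm_s": speed.ravel(),
            "heading_deg": heading.ravel(),
        }
    )


def instantaneous_speed(traj: TrajectorySet) -> pd.DataFrame:
    """Speed table (see :func:`compute_kinematics`)."""
    return compute_kinematics(traj)[["fly_id", "frame", "speed_mm_s"]]


def heading_angle(
    traj: TrajectorySet, min_disp: float = DEFAULT_MIN_DISP_MM
) -> pd.DataFrame:
    """Heading table (see :func:`compute_kinematics`)."""
    return compute_kinematics(traj, min_disp=min_disp)[
        ["fly_id", "frame", "heading_deg"]
    ]


@dataclass(frozen=True)
class AbnormalDirectionResult:
    """Fraction of defined-heading frames outside the normal angular range."""

    per_second: np.ndarray  # one fraction per second in the window (NaN if empty)
    accumulated: float
    window_seconds: int
    n_frames_defined: int


def abnormal_direction_fraction(
    kin: pd.DataFrame,
    fps: float = 60.0,
    window: int = 3,
    normal_range: tuple[float, float] = (-30.0, 30.0),
    per_fly: bool = False,
) -> AbnormalDirectionResult:
    """Fraction of movement outside ``normal_range`` of vertical.

    Headings are taken from a :func:`compute_kinematics` table.  Second s
    covers frames (s-1)*fps+1 .. s*fps.  By default fractions are
    frame-weighted (frames pooled across flies); ``per_fly=True`` averages
    each fly's own fraction instead.
    """
    lo, hi = normal_range
    if not lo < hi:
        raise InvalidArgumentError("normal_range must be increasing")
    fps_i = int(round(fps))
    sub = kin[kin["frame"] <= window * fps_i]
    defined = sub.dropna(subset=["heading_deg"])
    if defined.empty:
        raise UndefinedStatisticError(
            "no defined-heading frames in the analysis window"
        )
    abnormal = (defined["heading_deg"] < lo) | (defined["heading_deg"] > hi)

    per_second = np.full(window, np.nan)
    for s in range(1, window + 1):
        m = (defined["frame"] > (s - 1) * fps_i) & (defined["frame"] <= s * fps_i)
        if per_fly:
            grp = abnormal[m].groupby(defined.loc[m, "fly_id"]).mean()
            per_second[s - 1] = float(grp.mean()) if len(grp) else np.nan
        elif m.any():
            per_second[s - 1] = float(abnormal[m].mean())

    if per_fly:
        acc = float(abnormal.groupby(defined["fly_id"]).mean().mean())
    else:
        acc = float(abnormal.mean())
    return AbnormalDirectionResult(
        per_second=per_second,
        accumulated=acc,
        window_seconds=window,
        n_frames_defined=int(len(defined)),
    )


@dataclass(frozen=True)
class Histogram:
    """Normalized frequency histogram; ``empty`` flags zero usable records."""

    edges: np.ndarray
    frequencies: np.ndarray
    empty: bool = False


def speed_histogram(kin: pd.DataFrame, bin_width: float = 1.0) -> Histogram:
    """Speed histogram with frequencies summing to 1."""
    if bin_width <= 0:
        raise InvalidArgumentError("bin_width must be > 0")
    speeds = kin["speed_mm_s"].dropna().to_numpy()
    if speeds.size == 0:
        return Histogram(edges=np.array([0.0, bin_width]),
                         frequencies=np.array([0.0]), empty=True)
    top = max(speeds.max(), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(speeds, bins=edges)
    return Histogram(edges=edges, frequencies=counts / counts.sum())


def angular_histogram(kin: pd.DataFrame, bin_width: float = 15.0) -> Histogram:
    """Angular histogram over (-180, 180] with +-30 deg on bin edges.

    ``bin_width`` must divide 360 and 30 so that the normal-range
    boundaries fall on edges rather than bisecting a bin.
    """
    if bin_width <= 0:
        raise InvalidArgumentError("bin_width must be > 0")
    if 360 % bin_width or 30 % bin_width:
        raise InvalidArgumentError(
            "bin_width must divide both 360 and 30 degrees so that +-30 deg "
            "are bin edges"
        )
    headings = kin["heading_deg"].dropna().to_numpy()
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    if headings.size == 0:
        return Histogram(edges=edges, frequencies=np.zeros(len(edges) - 1),
                         empty=True)
    # histogram bins are [lo, hi) but the domain is (-180, 180]: fold exact
    # -180 onto +180 (already done upstream) and count 180 in the last bin
    counts, edges = np.histogram(np.clip(headings, -180.0, 180.0 - 1e-9),
                                 bins=edges)
    return Histogram(edges=edges, frequencies=counts / counts.sum())
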