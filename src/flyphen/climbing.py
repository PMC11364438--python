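"""Climbing Index (CI) computation and inference on CI curves.

The CI at each second of a 10 s trial is the weighted mean of height-bin
labels: the vial is split into ``n_bins`` equal height bins (bin 1 =
bottom), flies are counted per bin at each whole second (every ``fps``
frames), and CI(t) = sum_b b * count[t, b] / n_flies.  CI ranges from 1
(all flies at the bottom) to ``n_bins`` (all at the top).

Accumulated CI sums CI over the 10 s trial; the normalized accumulated CI
divides a test group's mean accumulated CI by the sham group's.  Group
curves are compared with a label-permutation test on whole curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidInputError, UndefinedStatisticError
from .trajectory import TrajectorySet

__all__ = [
    "BinOccupancy",
    "ClimbingCurve",
    "PermutationResult",
    "RatioEstimate",
    "accumulated_ci",
    "bin_positions",
    "ci_curve_permutation_test",
    "climbing_index",
    "curves_to_dataframe",
    "normalized_accumulated_ci",
]

N_SECONDS = 10


@dataclass
class BinOccupancy:
    """Fly counts per (second, height bin).  ``counts[t-1, b-1]`` is the
    number of flies in bin ``b`` at second ``t``; each row sums to
    ``n_flies``."""

    counts: np.ndarray  # (n_seconds, n_bins) non-negative integers
    n_flies: int
    n_bins: int = 10

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.n_bins:
            raise InvalidInputError(
                f"counts must have shape (n_seconds, {self.n_bins})"
            )
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")
        row_sums = self.counts.sum(axis=1)
        if not np.all(row_sums == self.n_flies):
            raise InvalidInputError(
                "each second's counts must sum to n_flies "
                f"(got row sums {row_sums.tolist()}, n_flies={self.n_flies})"
            )


@dataclass
class ClimbingCurve:
    """CI per second for one trial."""

    ci: np.ndarray  # (n_seconds,)
    n_flies: int
    n_bins: int = 10
    group: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.ci = np.asarray(self.ci, dtype=float)
        if self.ci.ndim != 1:
            raise InvalidInputError("ci must be one-dimensional")
        if np.any(self.ci < 1 - 1e-9) or np.any(self.ci > self.n_bins + 1e-9):
            raise InvalidInputError(f"ci values must lie in [1, {self.n_bins}]")


def bin_positions(
    traj: TrajectorySet, n_bins: int = 10, n_seconds: int = N_SECONDS
) -> BinOccupancy:
    """Count flies per height bin at each whole second.

    Positions are read at frames ``t * fps`` for t = 1..n_seconds (frame 0
    is the trial start, where all flies sit at the bottom by construction).
    Bins are half-open intervals [(b-1)*h/n_bins, b*h/n_bins) with the top
    boundary clamped into the top bin.
    """
    if n_bins < 1:
        raise InvalidArgumentError("n_bins must be >= 1")
    frames_per_second = int(round(traj.fps))
    needed = n_seconds * frames_per_second + 1
    if traj.duration_frames < needed:
        raise InvalidInputError(
            f"trajectory has {traj.duration_frames} frames; "
            f"{needed} needed for {n_seconds} s at {traj.fps} fps"
        )
    bin_height = traj.arena_height / n_bins
    counts = np.zeros((n_seconds, n_bins), dtype=int)
    for t in range(1, n_seconds + 1):
        y = traj.positions[:, t * frames_per_second, 1]
        bins = np.minimum(np.floor(y / bin_height).astype(int) + 1, n_bins)
        counts[t - 1] = np.bincount(bins - 1, minlength=n_bins)
    return BinOccupancy(counts=counts, n_flies=traj.n_flies, n_bins=n_bins)


def climbing_index(occ: BinOccupancy) -> ClimbingCurve:
    """CI(t) = (sum_b b * counts[t, b]) / n_flies."""
    if occ.n_flies == 0:
        raise UndefinedStatisticError("CI undefined for zero flies")
    bin_labels = np.arange(1, occ.n_bins + 1)
    ci = occ.counts @ bin_labels / occ.n_flies
    return ClimbingCurve(ci=ci, n_flies=occ.n_flies, n_bins=occ.n_bins)


def accumulated_ci(curve: ClimbingCurve) -> float:
    """Sum of CI over the trial's seconds (range [10, 100] for 10 bins)."""
    return float(np.sum(curve.ci))


@dataclass(frozen=True)
class RatioEstimate:
    """Ratio of group means with a delta-method standard error."""

    value: float
    se: float
    n_test: int
    n_sham: int


def normalized_accumulated_ci(
    test_curves: list[ClimbingCurve], sham_curves: list[ClimbingCurve]
) -> RatioEstimate:
    """Mean accumulated CI of the test group over the sham group's mean.

    The standard error is propagated by the delta method for a ratio of
    independent means: se(R) = R * sqrt(se_t^2/m_t^2 + se_s^2/m_s^2).
    """
    if not test_curves or not sham_curves:
        raise InvalidArgumentError("both curve lists must be non-empty")
    t = np.array([accumulated_ci(c) for c in test_curves])
    s = np.array([accumulated_ci(c) for c in sham_curves])
    mt, ms = t.mean(), s.mean()
    if ms == 0:
        raise UndefinedStatisticError("sham mean accumulated CI is zero")
    ratio = mt / ms
    se_t = t.std(ddof=1) / np.sqrt(len(t)) if len(t) > 1 else 0.0
    se_s = s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0
    rel = 0.0
    if mt != 0:
        rel += (se_t / mt) ** 2
    rel += (se_s / ms) ** 2
    se = abs(ratio) * np.sqrt(rel)
    return RatioEstimate(value=float(ratio), se=float(se), n_test=len(t), n_sham=len(s))


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_value: float
    n_perm: int
    n_a: int
    n_b: int


def ci_curve_permutation_test(
    group_a: list[ClimbingCurve],
    group_b: list[ClimbingCurve],
    n_perm: int = 9999,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation test comparing two sets of CI curves.

    The statistic is T = mean over seconds of |mean_a CI(t) - mean_b CI(t)|.
    Whole curves are resampled between labels; the p-value uses the
    add-one rule p = (1 + #{T* >= T}) / (n_perm + 1).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InvalidInputError("need >= 2 curves per group")
    if n_perm < 99:
        raise InvalidArgumentError("n_perm must be >= 99")
    a = np.stack([c.ci for c in group_a])
    b = np.stack([c.ci for c in group_b])
    if a.shape[1] != b.shape[1]:
        raise InvalidInputError("curves must share the same number of seconds")
    n_a = len(a)
    pooled = np.concatenate([a, b], axis=0)

    def stat(x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(np.abs(x.mean(axis=0) - y.mean(axis=0))))

    observed = stat(a, b)
    rng = np.random.default_rng(seed)
    n_total = len(pooled)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n_total)
        t_star = stat(pooled[idx[:n_a]], pooled[idx[n_a:]])
        if t_star >= observed - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(
        statistic=observed, p_value=p, n_perm=n_perm, n_a=len(a), n_b=len(b)
    )


def curves_to_dataframe(curves: list[ClimbingCurve]) -> pd.DataFrame:
    """Long-format table with columns trial_id, t, ci."""
    rows = []
    for c in curves:
        for t, v in enumerate(c.ci, start=1):
            rows.append({"trial_id": c.trial_id, "t": t, "ci": v})
    return pd.DataFrame(rows)
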