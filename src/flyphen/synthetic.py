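"""Synthetic data generators with known ground truth.

Three generators emulate the raw inputs of the phenotyping pipeline:

* :func:`simulate_trial` — startle-induced climbing trajectories in a
  28 x 90 mm arena at 60 fps (601 frames / 10 s);
* :func:`simulate_brain` — two-channel 3-D brain stacks (nuclear + F-actin)
  containing dark spherical vacuoles with a returned ground-truth list;
* :func:`simulate_survival` — right-censored Gompertz lifespans per group.

Every generator is bit-reproducible given its ``seed``.  Cohort presets
(:func:`default_params`) encode qualitative group orderings only; their
magnitudes are invented and documented in ``presets.json``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .brain import BrainMask, BrainStack, RegionLabel
from .errors import InvalidArgumentError, LookupError_, PlacementError
from .trajectory import (
    DEFAULT_ARENA_HEIGHT_MM,
    DEFAULT_ARENA_WIDTH_MM,
    DEFAULT_DURATION_FRAMES,
    DEFAULT_FPS,
    TrajectorySet,
)

__all__ = [
    "CohortParams",
    "GroundTruthVacuole",
    "SyntheticBrain",
    "default_params",
    "preset_labels",
    "simulate_brain",
    "simulate_survival",
    "simulate_trial",
]


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters encoding one experimental group.

    ``mean_speed`` (mm/s) is the mean of the per-fly gamma speed draw with
    shape ``speed_shape`` (``speed_shape = inf`` makes every fly move at
    exactly ``mean_speed``).  ``heading_sd`` (degrees) disperses per-frame
    headings about vertical; ``pause_prob`` is a per-frame Bernoulli pause.
    ``hazard_scale``/``hazard_shape`` parameterize the Gompertz lifespan
    hazard  h(t) = scale * exp(shape * t).
    """

    label: str
    mean_speed: float
    speed_shape: float
    heading_sd: float
    pause_prob: float
    startle_latency_mean: float
    hazard_scale: float
    hazard_shape: float
    n_flies_default: int = 15

    def __post_init__(self) -> None:
        for name in ("mean_speed", "heading_sd", "startle_latency_mean"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidArgumentError(f"{name} must be finite and >= 0, got {v}")
        if not self.speed_shape > 0:
            raise InvalidArgumentError("speed_shape must be > 0")
        if not 0.0 <= self.pause_prob <= 1.0:
            raise InvalidArgumentError("pause_prob must be in [0, 1]")
        for name in ("hazard_scale", "hazard_shape"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidArgumentError(f"{name} must be finite and > 0, got {v}")
        if self.n_flies_default < 1:
            raise InvalidArgumentError("n_flies_default must be >= 1")


def _load_presets() -> dict[str, dict]:
    text = resources.files("flyphen").joinpath("presets.json").read_text()
    raw = json.loads(text)
    return {k: v for k, v in raw.items() if not k.startswith("_")}


_PRESETS = _load_presets()


def preset_labels() -> list[str]:
    """Labels of the documented preset catalogue."""
    return sorted(_PRESETS)


def default_params(group_label: str) -> CohortParams:
    """Look up a preset cohort by label (e.g. ``"female_mated_D31Inj"``)."""
    try:
        raw = _PRESETS[group_label]
    except KeyError:
        raise LookupError_(
            f"unknown preset {group_label!r}; valid labels: {preset_labels()}"
        ) from None
    return CohortParams(label=group_label, **raw)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def simulate_trial(
    params: CohortParams,
    n_flies: int | None = None,
    seed: int = 0,
    *,
    n_frames: int = DEFAULT_DURATION_FRAMES,
    fps: float = DEFAULT_FPS,
    arena_width: float = DEFAULT_ARENA_WIDTH_MM,
    arena_height: float = DEFAULT_ARENA_HEIGHT_MM,
    start_y_max: float = 5.0,
    trial_id: str = "trial0",
) -> TrajectorySet:
    """Simulate one startle-induced climbing trial.

    Flies start in the bottom ``start_y_max`` mm.  After an exponential
    startle latency each fly moves every frame with a per-fly gamma speed
    and a per-frame wrapped-normal heading about vertical, pausing with
    probability ``params.pause_prob``.  x reflects at the side walls;
    y clamps at floor and ceiling (the assay reads height only).
    """
    if n_flies is None:
        n_flies = params.n_flies_default
    if n_flies < 1:
        raise InvalidArgumentError("n_flies must be >= 1")
    if n_frames < 1:
        raise InvalidArgumentError("n_frames must be >= 1")

    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, arena_width, size=n_flies)
    y = rng.uniform(0.0, start_y_max, size=n_flies)

    if params.startle_latency_mean > 0:
        latency = rng.exponential(params.startle_latency_mean, size=n_flies)
    else:
        latency = np.zeros(n_flies)

    if math.isinf(params.speed_shape):
        speeds = np.full(n_flies, params.mean_speed)
    elif params.mean_speed == 0:
        speeds = np.zeros(n_flies)
    else:
        speeds = rng.gamma(
            params.speed_shape, params.mean_speed / params.speed_shape, size=n_flies
        )
    step = speeds / fps  # mm per frame

    n_steps = n_frames - 1
    # bulk draws keep the frame loop to position updates only
    theta = np.deg2rad(rng.normal(0.0, params.heading_sd, size=(n_flies, n_steps)))
    moving = rng.random(size=(n_flies, n_steps)) >= params.pause_prob
    # fly starts moving once its latency has elapsed at the step's start time
    step_start = np.arange(n_steps) / fps
    active = step_start[None, :] >= latency[:, None]
    scale = step[:, None] * (moving & active)
    dx = scale * np.sin(theta)
    dy = scale * np.cos(theta)

    positions = np.empty((n_flies, n_frames, 2))
    positions[:, 0, 0] = x
    positions[:, 0, 1] = y
    for i in range(n_steps):
        x = x + dx[:, i]
        # single reflection is exact: one step is far shorter than the arena;
        # in-bounds values are left untouched bit-for-bit
        x = np.where(x < 0, -x, x)
        x = np.where(x > arena_width, 2 * arena_width - x, x)
        y = np.clip(y + dy[:, i], 0.0, arena_height)
        positions[:, i + 1, 0] = x
        positions[:, i + 1, 1] = y

    return TrajectorySet(
        positions=positions,
        fps=fps,
        arena_width=arena_width,
        arena_height=arena_height,
        trial_id=trial_id,
        group=params.label,
    )


# ---------------------------------------------------------------------------
# Brains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthVacuole:
    """One generated lesion: centroid in voxel coordinates (z, y, x),
    diameter in um, and the region it was placed in."""

    centroid: tuple[float, float, float]
    diameter: float
    region: str  # "neuropil" | "cortex"


@dataclass
class SyntheticBrain:
    """Generator output bundle: stack, ground-truth mask, ground-truth lesions."""

    stack: BrainStack
    mask: BrainMask
    vacuoles: list[GroundTruthVacuole]

    def truth_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(v) for v in self.vacuoles], fh, indent=2)


_CORTEX_INTENSITY = (200.0, 30.0)  # (nuclear, F-actin)
_NEUROPIL_INTENSITY = (30.0, 200.0)
_BACKGROUND_INTENSITY = 5.0


def simulate_brain(
    shape: tuple[int, int, int] = (80, 150, 200),
    voxel_size: float = 1.0,
    n_vacuoles: int = 10,
    diameter_range: tuple[float, float] = (5.0, 30.0),
    p_neuropil: float = 0.9,
    noise_sd: float = 10.0,
    seed: int = 0,
    *,
    cortex_thickness: float = 15.0,
    esophagus_radius: float = 6.0,
    min_sep_factor: float = 1.5,
    max_tries: int = 5000,
) -> SyntheticBrain:
    """Generate a two-channel brain stack with known vacuoles.

    The brain is an axis-aligned ellipsoid: a ``cortex_thickness``-um outer
    shell bright in the nuclear channel and a core bright in the F-actin
    channel, with a dark cylindrical esophagus corridor along the x axis
    (returned as the exclusion label).  ``n_vacuoles`` dark spheres with
    diameters uniform in ``diameter_range`` are placed without overlap
    (centre separation >= ``min_sep_factor`` x summed radii), each fully
    inside its region, in neuropil with probability ``p_neuropil``.
    Additive Gaussian noise of sd ``noise_sd`` is applied to both channels.

    Raises :class:`PlacementError` if a vacuole cannot be placed within
    ``max_tries`` rejection-sampling attempts.
    """
    d_lo, d_hi = diameter_range
    if not (0 < d_lo <= d_hi <= 50):
        raise InvalidArgumentError("diameter_range must satisfy 0 < lo <= hi <= 50 um")
    if not 0.0 <= p_neuropil <= 1.0:
        raise InvalidArgumentError("p_neuropil must be in [0, 1]")
    if n_vacuoles < 0:
        raise InvalidArgumentError("n_vacuoles must be >= 0")

    nz, ny, nx = shape
    vs = float(voxel_size)
    rng = np.random.default_rng(seed)

    center = np.array([(nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2]) * vs
    semi = np.array([0.42 * nz, 0.42 * ny, 0.45 * nx]) * vs  # um
    inner_semi = semi - cortex_thickness
    if np.any(inner_semi <= 0):
        raise InvalidArgumentError("shape too small to contain the brain model")

    # broadcast 1-D axis coordinates (um) instead of materializing a grid
    dz = (np.arange(nz) * vs - center[0])[:, None, None]
    dy = (np.arange(ny) * vs - center[1])[None, :, None]
    dx = (np.arange(nx) * vs - center[2])[None, None, :]
    r_outer = (dz / semi[0]) ** 2 + (dy / semi[1]) ** 2 + (dx / semi[2]) ** 2
    r_inner = (
        (dz / inner_semi[0]) ** 2
        + (dy / inner_semi[1]) ** 2
        + (dx / inner_semi[2]) ** 2
    )
    foreground = r_outer <= 1.0
    neuropil = r_inner <= 1.0
    cortex = foreground & ~neuropil
    # esophagus: axial corridor through the core, devoid of both stains
    axial_dist2 = dz**2 + dy**2  # (nz, ny, 1), broadcasts over x
    esophagus = foreground & (axial_dist2 <= esophagus_radius**2)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[cortex] = RegionLabel.CORTEX
    labels[neuropil] = RegionLabel.NEUROPIL
    labels[esophagus] = RegionLabel.EXCLUSION

    intensity = np.full((2,) + tuple(shape), _BACKGROUND_INTENSITY)
    for ch in range(2):
        intensity[ch][cortex] = _CORTEX_INTENSITY[ch]
        intensity[ch][neuropil] = _NEUROPIL_INTENSITY[ch]
        intensity[ch][esophagus] = _BACKGROUND_INTENSITY

    # --- vacuole placement (rejection sampling) -------------------------
    margin = 2.5 * vs  # keeps the 2-voxel classification shell inside the region
    placed: list[tuple[np.ndarray, float, str]] = []  # (centre um, radius um, region)
    for _ in range(n_vacuoles):
        region = "neuropil" if rng.random() < p_neuropil else "cortex"
        ok = False
        for _try in range(max_tries):
            d = rng.uniform(d_lo, d_hi)
            if region == "cortex":
                # the shell is thin; only lesions that fit inside it keep
                # their ground-truth label unambiguous
                d = min(d, cortex_thickness - 2 * margin - 1.0)
                if d <= 0:
                    continue
            r = d / 2
            c = center + (rng.uniform(-1, 1, size=3)) * semi
            shrink_out = semi - (r + margin)
            if np.any(shrink_out <= 0):
                continue
            f_out = np.sum(((c - center) / shrink_out) ** 2)
            shrink_in = inner_semi - (r + margin)
            if region == "neuropil":
                if np.any(shrink_in <= 0) or np.sum(((c - center) / shrink_in) ** 2) > 1:
                    continue
            else:
                # inside outer ellipsoid (with margin) but outside the inner
                # ellipsoid grown by r + margin, so the sphere stays in cortex
                if f_out > 1:
                    continue
                grown = inner_semi + (r + margin)
                if np.sum(((c - center) / grown) ** 2) <= 1:
                    continue
            # clear of esophagus corridor
            if math.hypot(c[0] - center[0], c[1] - center[1]) <= (
                esophagus_radius + r + margin
            ):
                continue
            # separation from already-placed lesions
            if any(
                np.linalg.norm(c - pc) < min_sep_factor * (r + pr)
                for pc, pr, _ in placed
            ):
                continue
            placed.append((c, r, region))
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place vacuole {len(placed) + 1}/{n_vacuoles} "
                f"after {max_tries} attempts"
            )

    truth: list[GroundTruthVacuole] = []
    for c, r, region in placed:
        # carve within the sphere's bounding box only (cheap for many lesions)
        lo = np.maximum(np.floor((c - r) / vs).astype(int) - 1, 0)
        hi = np.minimum(np.ceil((c + r) / vs).astype(int) + 2, shape)
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        bz = (np.arange(lo[0], hi[0]) * vs - c[0])[:, None, None]
        by = (np.arange(lo[1], hi[1]) * vs - c[1])[None, :, None]
        bx = (np.arange(lo[2], hi[2]) * vs - c[2])[None, None, :]
        sphere = bz**2 + by**2 + bx**2 <= r**2
        intensity[0][box][sphere] = _BACKGROUND_INTENSITY
        intensity[1][box][sphere] = _BACKGROUND_INTENSITY
        truth.append(
            GroundTruthVacuole(
                centroid=tuple(c / vs),  # voxel coordinates (z, y, x)
                diameter=2 * r,
                region=region,
            )
        )

    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    intensity = np.maximum(intensity, 0.0)

    stack = BrainStack(intensity=intensity, voxel_size=(vs, vs, vs))
    mask = BrainMask(labels=labels, voxel_size=(vs, vs, vs))
    return SyntheticBrain(stack=stack, mask=mask, vacuoles=truth)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def simulate_survival(
    params_by_group: dict[str, CohortParams],
    n_per_group: int,
    censor_time: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate right-censored Gompertz lifespans for each group.

    Returns a table with columns ``subject_id, group, time_days, event``
    (event 1 = died, 0 = censored at ``censor_time``).
    """
    if not params_by_group:
        raise InvalidArgumentError("params_by_group must be non-empty")
    if n_per_group < 1:
        raise InvalidArgumentError("n_per_group must be >= 1")
    if censor_time <= 0:
        raise InvalidArgumentError("censor_time must be > 0")

    rng = np.random.default_rng(seed)
    rows = []
    for group in params_by_group:  # caller-supplied order, deterministic
        p = params_by_group[group]
        a, b = p.hazard_scale, p.hazard_shape
        # Gompertz inversion: S(t) = exp(-(a/b)(e^{bt}-1));  -log U ~ Exp(1)
        e = rng.exponential(1.0, size=n_per_group)
        t = np.log1p(b * e / a) / b
        event = t <= censor_time
        time = np.minimum(t, censor_time)
        for i in range(n_per_group):
            rows.append(
                {
                    "subject_id": f"{group}_{i:04d}",
                    "group": group,
                    "time_days": float(time[i]),
                    "event": int(event[i]),
                }
            )
    return pd.DataFrame(rows)
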