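"""Vacuole detection and quantification in two-channel 3-D brain stacks.

A vacuole is a roughly round lesion devoid of both the nuclear and the
F-actin stain that is not part of a physiological structure (esophagus);
lesions range from 1 to 50 um in diameter and sit mostly in the neuropil.

Detection: candidate voxels are foreground voxels darker than
``dark_frac`` x the median foreground intensity; 26-connected 3-D
components are kept if their equivalent diameter lies in [d_min, d_max],
the circularity of their maximal-area z-slice is >= ``min_circ``, and
they overlap the exclusion mask by < 10%.  Each lesion's region
(neuropil vs cortex) is the majority label of a 2-voxel dilation shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .brain import BrainMask, BrainStack, RegionLabel
from .errors import (
    InvalidArgumentError,
    InvalidInputError,
    SegmentationError,
    UndefinedStatisticError,
)

__all__ = [
    "Vacuole",
    "VacuoleSet",
    "detect_vacuoles",
    "region_distribution",
    "segment_brain",
    "vacuolation_group_stats",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_MAX_EXCLUSION_OVERLAP = 0.10


@dataclass(frozen=True)
class Vacuole:
    """One detected lesion with geometry in physical units."""

    centroid_um: tuple[float, float, float]  # (z, y, x)
    volume_um3: float
    equivalent_diameter_um: float
    projected_area_um2: float
    circularity: float
    region: str  # "neuropil" | "cortex"


@dataclass
class VacuoleSet:
    """Detected lesions for one brain plus summary quantities."""

    vacuoles: list[Vacuole]

    @property
    def count(self) -> int:
        return len(self.vacuoles)

    @property
    def total_projected_area(self) -> float:
        return float(sum(v.projected_area_um2 for v in self.vacuoles))

    @property
    def total_volume(self) -> float:
        return float(sum(v.volume_um3 for v in self.vacuoles))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "centroid_z_um": v.centroid_um[0],
                "centroid_y_um": v.centroid_um[1],
                "centroid_x_um": v.centroid_um[2],
                "eq_diameter_um": v.equivalent_diameter_um,
                "volume_um3": v.volume_um3,
                "projected_area_um2": v.projected_area_um2,
                "circularity": v.circularity,
                "region": v.region,
            }
            for v in self.vacuoles
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "centroid_z_um", "centroid_y_um", "centroid_x_um",
                "eq_diameter_um", "volume_um3", "projected_area_um2",
                "circularity", "region",
            ],
        )

    def summary(self) -> dict:
        return {
            "count": self.count,
            "total_projected_area_um2": self.total_projected_area,
            "total_volume_um3": self.total_volume,
            "n_neuropil": sum(v.region == "neuropil" for v in self.vacuoles),
            "n_cortex": sum(v.region == "cortex" for v in self.vacuoles),
        }


def segment_brain(
    stack: BrainStack,
    exclusion_mask: np.ndarray | None = None,
    smooth_sigma: float = 2.0,
) -> BrainMask:
    """Segment a stack into background / cortex / neuropil / exclusion.

    Foreground is the largest 26-connected component of the smoothed
    combined intensity above an Otsu threshold, morphologically closed.
    Foreground voxels are cortex where the normalized nuclear channel
    dominates, neuropil otherwise.  The exclusion region is the supplied
    mask if given, else a detected low-intensity corridor spanning most of
    the foreground along the x axis (the esophagus).
    """
    combined = stack.intensity.sum(axis=0)
    smoothed = ndimage.gaussian_filter(combined, sigma=smooth_sigma)
    vmin, vmax = smoothed.min(), smoothed.max()
    if vmax <= 0:
        raise SegmentationError("empty stack: no positive intensity")
    if np.isclose(vmin, vmax):
        fg = np.ones(stack.shape, dtype=bool)  # uniform bright stack
    else:
        fg = smoothed > threshold_otsu(smoothed)
        if not fg.any():
            raise SegmentationError("thresholding produced an empty foreground")
        labels, n = ndimage.label(fg, structure=_STRUCT_26)
        if n > 1:
            sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
            fg = labels == (1 + int(np.argmax(sizes)))
        fg = ndimage.binary_closing(fg, structure=_STRUCT_26)
    if not fg.any():
        raise SegmentationError("segmentation produced an empty foreground")

    # per-channel normalization by a robust foreground scale
    norm = np.zeros_like(stack.intensity)
    for ch in range(2):
        scale = np.percentile(stack.intensity[ch][fg], 95)
        if scale <= 0:
            scale = 1.0
        norm[ch] = stack.intensity[ch] / scale
    cortex = fg & (norm[0] >= norm[1])
    neuropil = fg & ~cortex

    out = np.zeros(stack.shape, dtype=np.uint8)
    out[cortex] = RegionLabel.CORTEX
    out[neuropil] = RegionLabel.NEUROPIL

    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask).astype(bool)
        if excl.shape != stack.shape:
            raise InvalidInputError("exclusion mask shape mismatch")
    else:
        excl = _detect_axial_corridor(combined, fg)
    out[excl & fg] = RegionLabel.EXCLUSION
    return BrainMask(labels=out, voxel_size=stack.voxel_size)


def _detect_axial_corridor(combined: np.ndarray, fg: np.ndarray) -> np.ndarray:
    """Dark component spanning most of the foreground's x extent."""
    inside = fg & (combined < 0.3 * np.median(combined[fg]))
    if not inside.any():
        return np.zeros_like(fg)
    labels, n = ndimage.label(inside, structure=_STRUCT_26)
    xs = np.where(fg.any(axis=(0, 1)))[0]
    fg_extent = xs[-1] - xs[0] + 1
    corridor = np.zeros_like(fg)
    for obj_slice, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        if obj_slice is None:
            continue
        x_extent = obj_slice[2].stop - obj_slice[2].start
        if x_extent >= 0.6 * fg_extent:
            corridor |= labels == lab
    return corridor


def detect_vacuoles(
    stack: BrainStack,
    mask: BrainMask,
    d_min: float = 2.0,
    d_max: float = 50.0,
    dark_frac: float = 0.3,
    min_circ: float = 0.6,
    smooth_sigma: float = 1.0,
) -> VacuoleSet:
    """Detect stain-devoid lesions inside the brain foreground.

    ``d_min`` defaults to 2 um (not the biological 1 um lower bound): at
    1 um sampling a 1 um lesion is a single voxel and indistinguishable
    from noise.
    """
    if not 0 < d_min < d_max:
        raise InvalidArgumentError("need 0 < d_min < d_max")
    if mask.labels.shape != stack.shape:
        raise InvalidInputError("mask and stack geometries differ")
    vz, vy, vx = stack.voxel_size
    voxel_vol = stack.voxel_volume

    dark, combined, fg_median = candidate_voxels(
        stack, mask, dark_frac=dark_frac, smooth_sigma=smooth_sigma
    )

    # a 1-voxel dilation merges satellite cores with their parent lesion
    # without bridging distinct lesions (whose surface gap is larger)
    merged = ndimage.binary_dilation(dark, structure=_STRUCT_26, iterations=1)
    labels, n = ndimage.label(merged, structure=_STRUCT_26)
    labels[~dark] = 0  # seeds are the original dark voxels, grouped
    vacs: list[Vacuole] = []
    if n == 0:
        return VacuoleSet(vacuoles=[])
    excl = mask.exclusion
    objects = ndimage.find_objects(labels)
    claimed = np.zeros(labels.shape, dtype=bool)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        seed = labels[sl] == lab
        # the conservative dark threshold finds lesion cores; recover the
        # full extent with a half-maximum boundary so sizes are unbiased
        comp, sl = _refine_component(combined, seed, sl, fg_median, labels.shape)
        already = float((comp & claimed[sl]).sum())
        if comp.sum() and already / comp.sum() > 0.5:
            continue  # two dark cores refined onto the same lesion
        claimed[sl] |= comp
        n_vox = int(comp.sum())
        volume = n_vox * voxel_vol
        eq_d = (6.0 * volume / np.pi) ** (1.0 / 3.0)
        if not d_min <= eq_d <= d_max:
            continue
        # exclusion overlap (hard filter at 10%)
        overlap = float((comp & excl[sl]).sum()) / n_vox
        if overlap >= _MAX_EXCLUSION_OVERLAP:
            continue
        circ = _max_slice_circularity(comp)
        if circ < min_circ:
            continue
        region = _shell_region(mask.labels, comp, sl)
        if region is None:
            continue
        zc, yc, xc = ndimage.center_of_mass(comp)
        centroid = (
            (zc + sl[0].start) * vz,
            (yc + sl[1].start) * vy,
            (xc + sl[2].start) * vx,
        )
        projected = int(comp.any(axis=0).sum()) * vy * vx
        vacs.append(
            Vacuole(
                centroid_um=centroid,
                volume_um3=volume,
                equivalent_diameter_um=float(eq_d),
                projected_area_um2=float(projected),
                circularity=circ,
                region=region,
            )
        )
    return VacuoleSet(vacuoles=vacs)


def candidate_voxels(
    stack: BrainStack,
    mask: BrainMask,
    dark_frac: float = 0.3,
    smooth_sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Candidate lesion voxels: inside-brain voxels darker than
    ``dark_frac`` x the median foreground intensity.

    Returns (candidate mask, smoothed combined intensity, foreground median).
    The candidate set grows monotonically with ``dark_frac``.
    """
    combined = stack.intensity.sum(axis=0)
    if smooth_sigma > 0:
        combined = ndimage.gaussian_filter(combined, sigma=smooth_sigma)
    fg = mask.foreground | mask.exclusion  # lesion candidates live anywhere inside
    if not fg.any():
        raise InvalidInputError("mask has no foreground")
    fg_median = float(np.median(combined[fg]))
    dark = fg & (combined < dark_frac * fg_median)
    return dark, combined, fg_median


def _refine_component(
    combined: np.ndarray,
    seed: np.ndarray,
    sl: tuple,
    fg_median: float,
    shape: tuple,
    grow: int = 4,
    max_grow: int = 64,
) -> tuple[np.ndarray, tuple]:
    """Re-threshold a dark core at half maximum to recover the lesion edge.

    The refinement threshold is midway between the lesion's interior level
    and the surrounding tissue level, evaluated in a bounding box grown by
    ``grow`` voxels; the refined component is the 26-connected piece
    overlapping the seed core.  The box is regrown when the refined
    component touches its edge (a small satellite core of a large lesion).
    """
    while True:
        box = tuple(
            slice(max(s.start - grow, 0), min(s.stop + grow, dim))
            for s, dim in zip(sl, shape)
        )
        local = combined[box]
        offset = tuple(s.start - b.start for s, b in zip(sl, box))
        seed_in_box = np.zeros(local.shape, dtype=bool)
        seed_in_box[
            offset[0] : offset[0] + seed.shape[0],
            offset[1] : offset[1] + seed.shape[1],
            offset[2] : offset[2] + seed.shape[2],
        ] = seed
        core_level = float(np.median(local[seed_in_box]))
        thresh = 0.5 * (core_level + fg_median)
        refined = local < thresh
        lab, n = ndimage.label(refined, structure=_STRUCT_26)
        if n == 0:
            return seed_in_box, box
        overlap_labels = lab[seed_in_box]
        overlap_labels = overlap_labels[overlap_labels > 0]
        if overlap_labels.size == 0:
            return seed_in_box, box
        comp = lab == int(np.bincount(overlap_labels).argmax())
        clipped = any(
            (b.start > 0 and comp.take(0, axis=ax).any())
            or (b.stop < dim and comp.take(-1, axis=ax).any())
            for ax, (b, dim) in enumerate(zip(box, shape))
        )
        if not clipped or grow >= max_grow:
            return comp, box
        grow *= 2


def _max_slice_circularity(comp: np.ndarray) -> float:
    """Circularity 4*pi*A/P^2 of the component's maximal-area z-slice."""
    areas = comp.sum(axis=(1, 2))
    z = int(np.argmax(areas))
    plane = np.pad(comp[z], 1)  # pad so perimeter is well-defined at edges
    props = measure.regionprops(plane.astype(np.uint8))
    if not props:
        return 0.0
    p = props[0]
    if p.perimeter == 0:
        return 1.0  # single-voxel slice
    circ = 4.0 * np.pi * p.area / p.perimeter**2
    return float(min(circ, 1.0))


def _shell_region(all_labels: np.ndarray, comp: np.ndarray, sl: tuple) -> str | None:
    """Majority cortex/neuropil label in a 2-voxel dilation shell."""
    grown = tuple(
        slice(max(s.start - 3, 0), min(s.stop + 3, dim))
        for s, dim in zip(sl, all_labels.shape)
    )
    comp_g = np.zeros(tuple(g.stop - g.start for g in grown), dtype=bool)
    off = tuple(s.start - g.start for s, g in zip(sl, grown))
    comp_g[
        off[0] : off[0] + comp.shape[0],
        off[1] : off[1] + comp.shape[1],
        off[2] : off[2] + comp.shape[2],
    ] = comp
    shell = (
        ndimage.binary_dilation(comp_g, structure=_STRUCT_26, iterations=2) & ~comp_g
    )
    region_labels = all_labels[grown][shell]
    n_cortex = int((region_labels == RegionLabel.CORTEX).sum())
    n_neuropil = int((region_labels == RegionLabel.NEUROPIL).sum())
    if n_cortex == 0 and n_neuropil == 0:
        return None
    return "cortex" if n_cortex > n_neuropil else "neuropil"


def region_distribution(vacs: VacuoleSet) -> tuple[float, float]:
    """Percentages of lesions in (neuropil, cortex), summing to 100."""
    if vacs.count == 0:
        raise UndefinedStatisticError("no lesions to distribute")
    n_np = sum(v.region == "neuropil" for v in vacs.vacuoles)
    pct_np = 100.0 * n_np / vacs.count
    return (pct_np, 100.0 - pct_np)


def vacuolation_group_stats(
    per_brain: dict[str, list[VacuoleSet]], sham_group: str
) -> pd.DataFrame:
    """Group-level summaries normalized to the sham group's means.

    Returns one row per group with mean/median lesion count and total
    projected area, the sham-normalized versions, and Wilcoxon rank-sum
    p-values of each group against sham (count and area).
    """
    from .stats import wilcoxon_rank_sum  # local import: avoids cycle at import time

    if sham_group not in per_brain:
        raise InvalidInputError(f"sham group {sham_group!r} missing")
    for g, sets in per_brain.items():
        if not sets:
            raise InvalidInputError(f"group {g!r} is empty")

    counts = {g: np.array([v.count for v in sets]) for g, sets in per_brain.items()}
    areas = {
        g: np.array([v.total_projected_area for v in sets])
        for g, sets in per_brain.items()
    }
    sham_count_mean = counts[sham_group].mean()
    sham_area_mean = areas[sham_group].mean()

    rows = []
    for g in per_brain:
        row = {
            "group": g,
            "n_brains": len(per_brain[g]),
            "mean_count": counts[g].mean(),
            "median_count": float(np.median(counts[g])),
            "mean_total_area_um2": areas[g].mean(),
            "median_total_area_um2": float(np.median(areas[g])),
            "norm_count": (
                counts[g].mean() / sham_count_mean if sham_count_mean else np.nan
            ),
            "norm_total_area": (
                areas[g].mean() / sham_area_mean if sham_area_mean else np.nan
            ),
        }
        if g == sham_group:
            row["p_count_vs_sham"] = np.nan
            row["p_area_vs_sham"] = np.nan
        else:
            row["p_count_vs_sham"] = wilcoxon_rank_sum(
                counts[g].tolist(), counts[sham_group].tolist()
            ).p_value
            row["p_area_vs_sham"] = wilcoxon_rank_sum(
                areas[g].tolist(), areas[sham_group].tolist()
            ).p_value
        rows.append(row)
    return pd.DataFrame(rows)
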