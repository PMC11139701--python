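"""Spherical VOI definition, propagation and statistics.

The image-quality protocol uses one spherical lesion VOI centered on the
hottest lesion plus eight equal-radius background VOIs drawn in uptake-free
tissue.  The masks are drawn once on the reference grid and then *propagated*
unchanged to every duration × iteration image, so every condition is measured
through identical voxel sets.

Statistics extracted per condition: lesion mean/max, lesion peak (mean over a
1-cm³ neighborhood of the hottest lesion voxel — the SUVpeak convention),
background mean (mean of the 8 per-VOI means) and background SD (sample SD of
the voxels pooled across the 8 VOIs; an SD-across-VOI-means variant exists
behind a flag).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .image_io import ActivityImage
from .phantom import AcquisitionCondition

#: Radius (mm) of a 1 cm³ sphere, the peak neighborhood.
PEAK_SPHERE_RADIUS_MM = (3.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class VoiSpec:
    """Sphere in voxel coordinates (fractional indices allowed)."""

    center_vox: tuple[float, float, float]
    radius_mm: float
    role: str  # "lesion" | "background"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("VOI radius must be > 0")
        if self.role not in ("lesion", "background"):
            raise ValueError(f"VOI role must be 'lesion' or 'background', got {self.role!r}")


@dataclass(frozen=True)
class VoiReport:
    """Per-condition VOI statistics (all in kBq/ml)."""

    lesion_mean: float
    lesion_max: float
    lesion_peak: float
    bg_mean: float
    bg_sd: float
    condition: AcquisitionCondition

    def __post_init__(self) -> None:
        if self.lesion_max < self.lesion_mean:
            raise ValueError("lesion max cannot be below lesion mean")
        if self.bg_sd < 0:
            raise ValueError("background SD cannot be negative")


def sphere_mask(
    center_vox,
    radius_mm: float,
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    allow_clip: bool = False,
) -> np.ndarray:
    """Boolean mask of voxels whose *centers* lie within the sphere.

    The sphere must fit inside the grid unless ``allow_clip``; a radius too
    small to cover any voxel center is rejected.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    center_mm = [(c + 0.5) * v for c, v in zip(center_vox, voxel_size)]
    extent = [n * v for n, v in zip(grid_shape, voxel_size)]
    if not allow_clip:
        for c, e in zip(center_mm, extent):
            if c - radius_mm < 0 or c + radius_mm > e:
                raise ValueError(
                    f"sphere (center {tuple(center_mm)} mm, r={radius_mm} mm) "
                    f"extends outside the grid extent {tuple(extent)} mm"
                )
    axes = [
        ((np.arange(n, dtype=np.float64) + 0.5) * v - c) ** 2
        for n, v, c in zip(grid_shape, voxel_size, center_mm)
    ]
    gx, gy, gz = np.ix_(*axes)
    mask = gx + gy + gz <= radius_mm**2
    if not mask.any():
        raise ValueError(
            f"radius {radius_mm} mm covers no voxel centers on voxel grid {voxel_size} mm"
        )
    return mask


def lesion_peak(
    img: ActivityImage,
    lesion_mask: np.ndarray,
    peak_volume_ml: float = 1.0,
    shape: str = "sphere",
    boundary: str = "reject",
) -> float:
    """Mean over a 1-cm³ neighborhood of the hottest voxel in the lesion VOI.

    The neighborhood may extend beyond the lesion mask but not outside the
    grid; ``boundary='warn'`` clips it to the grid with a warning instead of
    rejecting.  ``shape='cube'`` uses an equal-volume cube.
    """
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    vals = np.where(lesion_mask, img.voxels, -np.inf)
    max_idx = np.unravel_index(int(np.argmax(vals)), img.voxels.shape)
    allow_clip = boundary == "warn"
    if shape == "sphere":
        radius = (3.0 * peak_volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        try:
            peak_mask = sphere_mask(max_idx, radius, img.voxels.shape, img.voxel_size,
                                    allow_clip=allow_clip)
        except ValueError as err:
            if "extends outside" in str(err):
                raise ValueError(f"peak neighborhood clipped by the grid boundary: {err}")
            raise
        if allow_clip:
            center_mm = [(c + 0.5) * v for c, v in zip(max_idx, img.voxel_size)]
            extent = [n * v for n, v in zip(img.voxels.shape, img.voxel_size)]
            if any(c - radius < 0 or c + radius > e for c, e in zip(center_mm, extent)):
                warnings.warn("peak neighborhood clipped by the grid boundary")
    elif shape == "cube":
        side = (peak_volume_ml * 1000.0) ** (1.0 / 3.0)
        half = side / 2.0
        sl = []
        for c, v, n in zip(max_idx, img.voxel_size, img.voxels.shape):
            center_mm = (c + 0.5) * v
            lo, hi = center_mm - half, center_mm + half
            if (lo < 0 or hi > n * v) and not allow_clip:
                raise ValueError("peak neighborhood clipped by the grid boundary")
            if lo < 0 or hi > n * v:
                warnings.warn("peak neighborhood clipped by the grid boundary")
            # voxel centers inside [lo, hi)
            idx = np.arange(n)
            inside = ((idx + 0.5) * v >= lo) & ((idx + 0.5) * v <= hi)
            sl.append(inside)
        peak_mask = np.ix_(*sl)
        return float(img.voxels[peak_mask].mean())
    else:
        raise ValueError(f"unknown peak shape {shape!r}")
    return float(img.voxels[peak_mask].mean())


def background_stats(
    img: ActivityImage,
    bg_masks: list[np.ndarray],
    sd_mode: str = "pooled",
) -> tuple[float, float]:
    """(bg_mean, bg_sd) from the background VOI set.

    bg_mean is the mean of the per-VOI means.  bg_sd is, by default, the
    sample SD (ddof=1) of all voxels pooled over the union of the VOIs — a
    voxel-noise SD; ``sd_mode='across_means'`` returns the SD of the per-VOI
    means instead.
    """
    if not bg_masks:
        raise ValueError("no background masks given")
    stack = np.stack([m.astype(np.int8) for m in bg_masks])
    if (stack.sum(axis=0) > 1).any():
        raise ValueError("background VOIs overlap")
    means = [float(img.voxels[m].mean()) for m in bg_masks]
    bg_mean = float(np.mean(means))
    if sd_mode == "pooled":
        pooled = np.concatenate([img.voxels[m] for m in bg_masks])
        bg_sd = float(pooled.std(ddof=1))
    elif sd_mode == "across_means":
        bg_sd = float(np.std(means, ddof=1))
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    return bg_mean, bg_sd


def build_voi_masks(
    vois: list[VoiSpec],
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Materialize the study VOI set: exactly 1 lesion + exactly 8 background.

    Background VOIs must not overlap each other or the lesion VOI.
    """
    lesions = [v for v in vois if v.role == "lesion"]
    bgs = [v for v in vois if v.role == "background"]
    if len(lesions) != 1 or len(bgs) != 8:
        raise ValueError(
            f"a study needs exactly 1 lesion and 8 background VOIs, "
            f"got {len(lesions)} and {len(bgs)}"
        )
    lesion = sphere_mask(lesions[0].center_vox, lesions[0].radius_mm, grid_shape, voxel_size)
    bg_masks = [sphere_mask(b.center_vox, b.radius_mm, grid_shape, voxel_size) for b in bgs]
    stack = np.stack([m.astype(np.int8) for m in bg_masks])
    if (stack.sum(axis=0) > 1).any():
        raise ValueError("background VOIs overlap")
    if any((m & lesion).any() for m in bg_masks):
        raise ValueError("a background VOI overlaps the lesion VOI")
    return lesion, bg_masks


def extract_report(
    img: ActivityImage,
    lesion_mask: np.ndarray,
    bg_masks: list[np.ndarray],
    condition: AcquisitionCondition,
    sd_mode: str = "pooled",
    peak_boundary: str = "reject",
) -> VoiReport:
    """All VOI statistics of one condition image."""
    lesion_vals = img.voxels[lesion_mask]
    bg_mean, bg_sd = background_stats(img, bg_masks, sd_mode=sd_mode)
    return VoiReport(
        lesion_mean=float(lesion_vals.mean()),
        lesion_max=float(lesion_vals.max()),
        lesion_peak=lesion_peak(img, lesion_mask, boundary=peak_boundary),
        bg_mean=bg_mean,
        bg_sd=bg_sd,
        condition=condition,
    )


def propagate(
    vois: list[VoiSpec],
    images: dict[AcquisitionCondition, ActivityImage],
    sd_mode: str = "pooled",
) -> list[VoiReport]:
    """Apply the identical voxel masks to every condition image.

    All images must share the reference grid (shape and voxel size); a
    mismatch is rejected naming both grids.
    """
    if not images:
        raise ValueError("no condition images given")
    conds = list(images)
    ref = images[conds[0]]
    lesion_mask, bg_masks = build_voi_masks(vois, ref.voxels.shape, ref.voxel_size)
    reports = []
    for cond in conds:
        img = images[cond]
        if img.voxels.shape != ref.voxels.shape or img.voxel_size != ref.voxel_size:
            raise ValueError(
                f"condition {cond} grid {img.voxels.shape}/{img.voxel_size} does not match "
                f"reference grid {ref.voxels.shape}/{ref.voxel_size}"
            )
        reports.append(extract_report(img, lesion_mask, bg_masks, cond, sd_mode=sd_mode))
    return reports


def default_voi_specs(spec) -> list[VoiSpec]:
    """Default VOI placements for the default phantom geometry.

    One 12-mm lesion VOI at the (first) tumor center and eight 12-mm
    background VOIs on the lesion's transaxial slice, in the uptake-free body
    background anterior and posterior of the liver.
    """
    vs = spec.voxel_size
    tumor = spec.tumors[0]

    def mm_to_vox(p_mm):
        return tuple(p / v - 0.5 for p, v in zip(p_mm, vs))

    z = tumor.center_mm[2]
    radius = 10.0
    vois = [VoiSpec(mm_to_vox(tumor.center_mm), radius, "lesion")]
    for y in (25.0, 185.0):
        for x in (30.0, 80.0, 130.0, 180.0):
            vois.append(VoiSpec(mm_to_vox((x, y, z)), radius, "background"))
    return vois
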