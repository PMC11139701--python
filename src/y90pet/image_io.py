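"""Volumetric containers and NIfTI round-trip I/O.

An :class:`ActivityImage` is a 3-D voxel grid of activity concentration in
kBq/ml on a regular anisotropic grid; a :class:`SegmentationSet` is a
co-registered integer label map whose labels name dosimetric compartments
(tumor, normal liver, left/right lung, background).  Everything downstream
(VOI statistics, dose maps) operates on these two containers, which must share
one grid — there is no resampling in this package.

Conventions: axis order (x, y, z) with y the anterior-posterior axis; 0-based
indices; voxel *centers* at ``(index + 0.5) * voxel_size`` mm; concentrations
are always kBq/ml internally (unit converters belong at the boundary).
"""

from __future__ import annotations

import json
import math
import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: Canonical compartment roles a label may map to.
KNOWN_ROLES = frozenset(
    {"background", "liver_normal", "tumor", "lung_left", "lung_right"}
)

Y90_HALF_LIFE_H = 64.05


@dataclass
class ActivityImage:
    """Decay-corrected activity-concentration volume (kBq/ml)."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    reference_time_h: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("activity image contains non-finite values")
        if np.any(self.voxels < 0):
            raise ValueError("activity concentrations must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive lengths, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (mm³ / 1000)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    @property
    def total_activity_kbq(self) -> float:
        """Total imaged activity: Σ concentration × voxel volume."""
        return float(self.voxels.sum() * self.voxel_volume_ml)

    def with_voxels(self, voxels: np.ndarray) -> "ActivityImage":
        return replace(self, voxels=voxels)


@dataclass
class SegmentationSet:
    """Integer label map plus the mapping label → compartment role."""

    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be an integer array")
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3-D label map, got shape {self.labels.shape}")
        self.label_names = {int(k): str(v) for k, v in self.label_names.items()}
        unknown = set(self.label_names.values()) - KNOWN_ROLES
        if unknown:
            raise ValueError(f"unknown compartment roles: {sorted(unknown)}")
        present = set(np.unique(self.labels).tolist())
        unnamed = present - set(self.label_names)
        if unnamed:
            raise ValueError(f"labels {sorted(unnamed)} present in map but not named")

    def mask(self, *roles: str) -> np.ndarray:
        """Boolean mask of all voxels whose label maps to one of *roles*."""
        bad = set(roles) - KNOWN_ROLES
        if bad:
            raise ValueError(f"unknown roles requested: {sorted(bad)}")
        wanted = [lab for lab, role in self.label_names.items() if role in roles]
        return np.isin(self.labels, wanted)

    @property
    def whole_liver_mask(self) -> np.ndarray:
        """Whole liver = tumor ∪ normal liver (derived, never stored)."""
        return self.mask("tumor", "liver_normal")

    @property
    def lung_mask(self) -> np.ndarray:
        return self.mask("lung_left", "lung_right")


def validate_paired(img: ActivityImage, segs: SegmentationSet) -> None:
    """Reject an image/label-map pair that does not share one grid."""
    if img.voxels.shape != segs.labels.shape:
        raise ValueError(
            f"image grid {img.voxels.shape} does not match label-map grid {segs.labels.shape}"
        )


# ---------------------------------------------------------------------------
# decay correction
# ---------------------------------------------------------------------------

def _as_hours(t) -> float:
    if t is None:
        raise ValueError("decay correction requires both timestamps; got None")
    if isinstance(t, _dt.datetime):
        return t.timestamp() / 3600.0
    return float(t)


def decay_correct(
    img: ActivityImage,
    from_time,
    to_time,
    half_life_h: float = Y90_HALF_LIFE_H,
) -> ActivityImage:
    """Rescale concentrations from one reference time to another.

    ``from_time``/``to_time`` are hours (floats) or ``datetime`` objects.
    Correcting back to an earlier time scales voxels *up* by
    ``2**((from - to)/half_life)``; the transform forms a group, so A→B→C
    equals A→C.
    """
    if not (half_life_h > 0 and math.isfinite(half_life_h)):
        raise ValueError(f"half-life must be positive and finite, got {half_life_h}")
    dt_h = _as_hours(from_time) - _as_hours(to_time)
    factor = 2.0 ** (dt_h / half_life_h)
    return ActivityImage(
        voxels=img.voxels * factor,
        voxel_size=img.voxel_size,
        reference_time_h=_as_hours(to_time),
    )


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def _affine(voxel_size) -> np.ndarray:
    aff = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    return aff


def write_image(img: ActivityImage, path) -> None:
    """Write a volume as NIfTI-1 with voxel size in the header (float64)."""
    nii = nib.Nifti1Image(img.voxels, _affine(img.voxel_size))
    nii.header.set_zooms(img.voxel_size)
    if img.reference_time_h is not None:
        nii.header["descrip"] = f"kBq/ml;ref_time_h={img.reference_time_h:.6g}".encode()
    else:
        nii.header["descrip"] = b"kBq/ml"
    nib.save(nii, str(path))


def read_image(path) -> ActivityImage:
    nii = nib.load(str(path))
    zooms = tuple(float(z) for z in nii.header.get_zooms()[:3])
    descrip = bytes(nii.header["descrip"]).decode(errors="replace")
    ref: float | None = None
    if "ref_time_h=" in descrip:
        ref = float(descrip.split("ref_time_h=")[1].split(";")[0].rstrip("\x00"))
    return ActivityImage(
        voxels=np.asarray(nii.dataobj, dtype=np.float64),
        voxel_size=zooms,
        reference_time_h=ref,
    )


def write_segmentation(segs: SegmentationSet, path) -> None:
    """Integer NIfTI plus a JSON sidecar mapping label → role."""
    path = Path(path)
    nii = nib.Nifti1Image(segs.labels.astype(np.int16), np.eye(4))
    nib.save(nii, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar = Path(str(sidecar) + ".labels.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in segs.label_names.items()}, indent=1))


def read_segmentation(path) -> SegmentationSet:
    path = Path(path)
    nii = nib.load(str(path))
    sidecar = path.with_suffix("").with_suffix("")
    sidecar = Path(str(sidecar) + ".labels.json")
    names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return SegmentationSet(labels=np.asarray(nii.dataobj, dtype=np.int16), label_names=names)
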