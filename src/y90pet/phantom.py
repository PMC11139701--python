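"""Synthetic ⁹⁰Y liver phantom and acquisition simulator.

This module stands in for a patient cohort: it builds a piecewise-constant
activity phantom (liver with hot tumor(s), low-uptake lungs, a soft-tissue
background floor), then emulates what a reconstructed PET image of it would
look like for a given scan duration and OSEM iteration number.

The emulation is deliberately *not* a reconstruction.  It is the composition

    truth  →  isotropic Gaussian PSF blur  →  count-statistics noise,

where the per-voxel noise SD follows the counting law

    SD(v) = g(iterations) · sqrt( blurred(v) / (c · duration) ),

with ``c`` the counts-per-(kBq/ml)-per-minute calibration and ``g`` a
monotone gain that encodes the empirical fact that OSEM noise grows with the
iteration number (g(2) = 1 by convention).  The Gaussian approximation to
Poisson counting noise is valid away from zero; negative excursions are
clipped at 0 and the calibration default keeps every tissue ≥ ~4 SD from the
clip, so the expectation of the output equals the blurred truth to high
accuracy.

Planar anterior/posterior projections (for the geometric-mean lung-shunt
estimate) are parallel sums along the anterior-posterior axis with
per-organ multiplicative attenuation factors and optional Poisson noise.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .image_io import ActivityImage, SegmentationSet, validate_paired

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

LABELS = {"background": 0, "liver_normal": 1, "tumor": 2, "lung_left": 3, "lung_right": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in mm."""

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes_mm):
            raise ValueError(f"ellipsoid semi-axes must be > 0, got {self.semiaxes_mm}")


@dataclass(frozen=True)
class TumorSphere:
    center_mm: tuple[float, float, float]
    radius_mm: float
    concentration_kbq_ml: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("tumor radius must be > 0")
        if self.concentration_kbq_ml < 0:
            raise ValueError("tumor concentration must be >= 0")


@dataclass
class PhantomSpec:
    """Full description of one synthetic patient.

    Default voxel size 3.3 × 3.3 × 1.65 mm matches a long-axial-FOV PET
    reconstruction grid; concentrations are in kBq/ml.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (3.3, 3.3, 1.65)
    liver: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((100.0, 105.0, 35.0), (65.0, 55.0, 28.0))
    )
    tumors: tuple[TumorSphere, ...] = (
        TumorSphere((120.0, 105.0, 35.0), 20.0, 6000.0),
    )
    liver_background_conc: float = 750.0
    lungs: tuple[Ellipsoid, Ellipsoid] = (
        Ellipsoid((70.0, 105.0, 85.0), (28.0, 40.0, 18.0)),
        Ellipsoid((130.0, 105.0, 85.0), (28.0, 40.0, 18.0)),
    )
    lung_conc: float = 10.0
    body_background_conc: float = 500.0
    scatter_halo: Ellipsoid | None = field(
        default_factory=lambda: Ellipsoid((105.6, 105.6, 35.0), (160.0, 160.0, 30.0))
    )
    far_background_conc: float = 0.0
    psf_fwhm_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        for conc in (self.liver_background_conc, self.lung_conc,
                     self.body_background_conc, self.far_background_conc):
            if conc < 0:
                raise ValueError("concentrations must be >= 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("PSF FWHM must be >= 0")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.grid_shape, self.voxel_size))

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["liver"] = Ellipsoid(tuple(d["liver"]["center_mm"]), tuple(d["liver"]["semiaxes_mm"]))
        d["tumors"] = tuple(
            TumorSphere(tuple(t["center_mm"]), t["radius_mm"], t["concentration_kbq_ml"])
            for t in d["tumors"]
        )
        d["lungs"] = tuple(
            Ellipsoid(tuple(e["center_mm"]), tuple(e["semiaxes_mm"])) for e in d["lungs"]
        )
        if d.get("scatter_halo") is not None:
            d["scatter_halo"] = Ellipsoid(
                tuple(d["scatter_halo"]["center_mm"]),
                tuple(d["scatter_halo"]["semiaxes_mm"]),
            )
        d["grid_shape"] = tuple(d["grid_shape"])
        d["voxel_size"] = tuple(d["voxel_size"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class AcquisitionCondition:
    """One cell of the duration × iterations factorial."""

    duration_min: float
    iterations: int
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if not self.duration_min > 0:
            raise ValueError(f"scan duration must be > 0 min, got {self.duration_min}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if self.replicate_index < 0:
            raise ValueError("replicate_index must be >= 0")


DEFAULT_DURATIONS_MIN = (20.0, 15.0, 10.0, 5.0, 1.0)
DEFAULT_ITERATIONS = (2, 4, 6, 8)


@dataclass
class NoiseModel:
    """Counting-noise calibration plus the iteration → SD-gain map.

    ``counts_per_kbqml_min`` is the expected number of detected counts per
    voxel per kBq/ml per minute; it sets the absolute noise level.  Setting it
    to ``math.inf`` yields the noiseless limit (output = blurred truth).
    """

    counts_per_kbqml_min: float = 0.04
    iteration_noise_gain: dict[int, float] = field(
        default_factory=lambda: {2: 1.0, 4: 1.15, 6: 1.3, 8: 1.45}
    )

    def __post_init__(self) -> None:
        if not self.counts_per_kbqml_min > 0:
            raise ValueError("counts calibration must be > 0")
        its = sorted(self.iteration_noise_gain)
        gains = [self.iteration_noise_gain[i] for i in its]
        if any(b < a for a, b in zip(gains, gains[1:])):
            raise ValueError("iteration noise gain must be non-decreasing in iterations")
        if 2 in self.iteration_noise_gain and self.iteration_noise_gain[2] != 1.0:
            raise ValueError("gain at 2 iterations is the reference and must equal 1.0")

    def gain(self, iterations: int) -> float:
        """SD gain for an iteration count; linear interpolation off-grid."""
        its = np.array(sorted(self.iteration_noise_gain), dtype=float)
        gains = np.array([self.iteration_noise_gain[int(i)] for i in its])
        return float(np.interp(iterations, its, gains))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _center_grids(spec: PhantomSpec):
    """Open mm-coordinate grids of voxel centers, (index + 0.5) * size."""
    axes = [
        (np.arange(n, dtype=np.float64) + 0.5) * v
        for n, v in zip(spec.grid_shape, spec.voxel_size)
    ]
    return np.ix_(*axes)


def _inside_ellipsoid(grids, ell: Ellipsoid) -> np.ndarray:
    x, y, z = grids
    cx, cy, cz = ell.center_mm
    ax, ay, az = ell.semiaxes_mm
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _inside_sphere(grids, center_mm, radius_mm) -> np.ndarray:
    x, y, z = grids
    cx, cy, cz = center_mm
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_mm**2


def build_ground_truth(spec: PhantomSpec) -> tuple[ActivityImage, SegmentationSet]:
    """Voxelize the phantom into an activity image and exclusive label map.

    Tumor voxels carry the tumor concentration (they overwrite the liver
    background); tumors overlapping lung tissue, lungs overlapping the liver,
    or tumors leaking outside the liver are rejected.
    """
    grids = _center_grids(spec)
    liver = _inside_ellipsoid(grids, spec.liver)
    lung_l = _inside_ellipsoid(grids, spec.lungs[0])
    lung_r = _inside_ellipsoid(grids, spec.lungs[1])
    if np.any((lung_l | lung_r) & liver):
        raise ValueError("lung regions overlap the liver ellipsoid")
    if np.any(lung_l & lung_r):
        raise ValueError("the two lung regions overlap each other")

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    if spec.scatter_halo is None:
        conc = np.full(spec.grid_shape, spec.body_background_conc, dtype=np.float64)
    else:
        # The image-noise/scatter baseline is confined to an abdominal halo
        # around the liver; the rest of the body (notably the thorax around
        # the lungs) stays at the far-background level.
        conc = np.full(spec.grid_shape, spec.far_background_conc, dtype=np.float64)
        conc[_inside_ellipsoid(grids, spec.scatter_halo)] = spec.body_background_conc

    labels[liver] = LABELS["liver_normal"]
    conc[liver] = spec.liver_background_conc
    for name, mask in (("lung_left", lung_l), ("lung_right", lung_r)):
        labels[mask] = LABELS[name]
        conc[mask] = spec.lung_conc

    for i, tumor in enumerate(spec.tumors):
        sphere = _inside_sphere(grids, tumor.center_mm, tumor.radius_mm)
        if not sphere.any():
            raise ValueError(f"tumor {i} covers no voxel centers")
        if np.any(sphere & (lung_l | lung_r)):
            raise ValueError(f"tumor {i} overlaps lung tissue — conflicting labels")
        if np.any(sphere & ~liver):
            raise ValueError(f"tumor {i} extends outside the liver ellipsoid")
        labels[sphere] = LABELS["tumor"]
        conc[sphere] = tumor.concentration_kbq_ml

    img = ActivityImage(conc, spec.voxel_size, reference_time_h=0.0)
    segs = SegmentationSet(labels, dict(LABEL_NAMES))
    return img, segs


# ---------------------------------------------------------------------------
# emission/reconstruction surrogate
# ---------------------------------------------------------------------------

def apply_psf(truth: ActivityImage, psf_fwhm_mm: float) -> ActivityImage:
    """Isotropic Gaussian blur of the stated FWHM (mm), anisotropy-aware."""
    if psf_fwhm_mm < 0:
        raise ValueError("PSF FWHM must be >= 0")
    if psf_fwhm_mm == 0:
        return truth.with_voxels(truth.voxels.copy())
    sigma_vox = [psf_fwhm_mm * FWHM_TO_SIGMA / v for v in truth.voxel_size]
    return truth.with_voxels(gaussian_filter(truth.voxels, sigma_vox, mode="nearest"))


def condition_seed_sequence(seed: int, cond: AcquisitionCondition) -> np.random.SeedSequence:
    """Deterministic child seed per (master seed, condition)."""
    return np.random.SeedSequence(
        [int(seed), int(round(cond.duration_min * 1000)), int(cond.iterations),
         int(cond.replicate_index)]
    )


def simulate_acquisition(
    truth: ActivityImage,
    cond: AcquisitionCondition,
    noise: NoiseModel,
    psf_fwhm_mm: float = 6.0,
    seed: int = 0,
    blurred: ActivityImage | None = None,
) -> ActivityImage:
    """Emulate one reconstructed image for a scan-duration/iteration cell.

    ``blurred`` may carry a precomputed ``apply_psf(truth, psf_fwhm_mm)`` to
    amortize the blur across replicates; correctness is unaffected.
    """
    if blurred is None:
        blurred = apply_psf(truth, psf_fwhm_mm)
    mean = blurred.voxels
    if math.isinf(noise.counts_per_kbqml_min):
        out = mean.copy()
    else:
        sd = noise.gain(cond.iterations) * np.sqrt(
            mean / (noise.counts_per_kbqml_min * cond.duration_min)
        )
        rng = np.random.default_rng(condition_seed_sequence(seed, cond))
        out = np.clip(mean + rng.standard_normal(mean.shape) * sd, 0.0, None)
    return ActivityImage(out, truth.voxel_size, reference_time_h=truth.reference_time_h)


# ---------------------------------------------------------------------------
# planar projections for the lung-shunt estimate
# ---------------------------------------------------------------------------

@dataclass
class PlanarImage:
    """2-D count image in the (x, z) plane (projection along y)."""

    pixels: np.ndarray
    pixel_size_mm: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"planar image must be 2-D, got shape {self.pixels.shape}")
        if np.any(self.pixels < 0) or not np.all(np.isfinite(self.pixels)):
            raise ValueError("planar counts must be finite and non-negative")


def _factor_volume(segs: SegmentationSet, factors: dict[str, float] | None) -> np.ndarray:
    out = np.ones(segs.labels.shape, dtype=np.float64)
    if factors:
        for role, f in factors.items():
            out[segs.mask(role)] = f
    return out


def simulate_planar_pair(
    truth: ActivityImage,
    segs: SegmentationSet,
    anterior_factors: dict[str, float] | None = None,
    posterior_factors: dict[str, float] | None = None,
    counts_per_kbq: float = 1.0,
    poisson: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[PlanarImage, PlanarImage]:
    """Anterior/posterior parallel projections of counts ∝ activity.

    Attenuation is a multiplicative per-organ factor (role → factor), possibly
    different between the two views; the geometric mean of the two views
    cancels reciprocal factors exactly.  Poisson noise is optional.
    """
    validate_paired(truth, segs)
    counts3d = truth.voxels * truth.voxel_volume_ml * counts_per_kbq
    ant = (counts3d * _factor_volume(segs, anterior_factors)).sum(axis=1)
    post = (counts3d * _factor_volume(segs, posterior_factors)).sum(axis=1)
    if poisson:
        if rng is None:
            rng = np.random.default_rng()
        ant = rng.poisson(ant).astype(np.float64)
        post = rng.poisson(post).astype(np.float64)
    px = (truth.voxel_size[0], truth.voxel_size[2])
    return PlanarImage(ant, px), PlanarImage(post, px)


def project_roi(segs: SegmentationSet, *roles: str) -> np.ndarray:
    """2-D ROI in the planar (x, z) plane: any voxel of the role along y."""
    return segs.mask(*roles).any(axis=1)


# ---------------------------------------------------------------------------
# study defaults
# ---------------------------------------------------------------------------

def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """The default synthetic patient used throughout the study pipeline."""
    return PhantomSpec(seed=seed)


def maa_variant(
    spec: PhantomSpec,
    tumor_scale: float = 1.09,
    lung_scale: float = 2.0,
) -> PhantomSpec:
    """Pre-treatment (MAA surrogate) phantom: a deliberate mis-specification.

    The MAA distribution over-represents tumor uptake slightly and lung
    shunting more strongly, and carries no soft-tissue background (the tracer
    is confined to the hepatic arterial bed and shunted lung), emulating the
    systematic predicted-vs-actual discrepancies seen clinically.
    """
    return replace(
        spec,
        tumors=tuple(
            replace(t, concentration_kbq_ml=t.concentration_kbq_ml * tumor_scale)
            for t in spec.tumors
        ),
        lung_conc=spec.lung_conc * lung_scale,
        body_background_conc=0.0,
        far_background_conc=0.0,
    )
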