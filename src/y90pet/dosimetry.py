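"""Voxel and compartment dosimetry for permanently implanted ⁹⁰Y.

Local deposition model (LDM): every β decay deposits its mean energy in the
voxel where it occurs, so for a decay-corrected concentration image the voxel
dose is a closed form,

    dose [Gy] = C [Bq/ml] · τ [s] · Ē_β [J] / ρ [kg/ml],

with τ = T½/ln 2 the permanent-implant residence time.  No photon transport,
no dose-point kernels: this is the homogeneous kBq/ml → Gy conversion used by
multi-compartment MIRD software.

Compartment (partition-model) doses distribute a known activity over the
segmented compartments in proportion to their image counts, with the lung
compartment fed by the planar geometric-mean shunt fraction:

    D_c [Gy] = k · A_c [GBq] / m_c [kg],   k = τ · Ē_β · 1e9  (≈ 49.4 Gy·kg/GBq)

DVH statistics use the nearest-rank convention: D_x is the dose at rank
⌈x/100·n⌉ of the descending-sorted voxel doses (a linear-interpolation
variant sits behind a flag), so D2 ≥ D50 ≥ D70 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import PhysicsConstants
from .image_io import ActivityImage, SegmentationSet, validate_paired
from .phantom import PlanarImage

#: Mean lung dose above which radio-pneumonitis risk is unacceptable.
LUNG_DOSE_LIMIT_GY = 20.0


@dataclass
class DoseMap:
    """Voxel absorbed-dose grid (Gy) sharing the activity image geometry."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if np.any(self.voxels < 0) or not np.all(np.isfinite(self.voxels)):
            raise ValueError("dose map must be finite and non-negative")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0


@dataclass(frozen=True)
class DvhSummary:
    d2: float
    d50: float
    d70: float
    dmean: float
    compartment: str
    voxel_count: int

    def __post_init__(self) -> None:
        if not (self.d2 >= self.d50 >= self.d70):
            raise ValueError(f"DVH ordering violated: D2={self.d2}, D50={self.d50}, D70={self.d70}")

    def as_dict(self) -> dict[str, float]:
        return {"d2": self.d2, "d50": self.d50, "d70": self.d70, "dmean": self.dmean}


@dataclass(frozen=True)
class ShuntResult:
    lsf: float
    gm_lung_counts: float
    gm_liver_counts: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lsf <= 1.0:
            raise ValueError(f"lung shunt fraction must lie in [0, 1], got {self.lsf}")


# ---------------------------------------------------------------------------
# voxel dose
# ---------------------------------------------------------------------------

def density_map(segs: SegmentationSet, constants: PhysicsConstants) -> np.ndarray:
    """Per-voxel tissue density (g/ml) derived from segmentation roles."""
    out = np.full(segs.labels.shape, constants.soft_tissue_density_g_ml, dtype=np.float64)
    out[segs.lung_mask] = constants.lung_density_g_ml
    return out


def voxel_ldm_dose(
    img: ActivityImage,
    constants: PhysicsConstants,
    density_g_ml: np.ndarray | float,
) -> DoseMap:
    """Local-deposition-model dose map from a decay-corrected image.

    ``density_g_ml`` is a per-voxel density array (see :func:`density_map`)
    or a scalar for homogeneous media.  Any labeled voxel must have a
    positive, finite density.
    """
    rho = np.asarray(density_g_ml, dtype=np.float64)
    if rho.shape not in ((), img.voxels.shape):
        raise ValueError(
            f"density grid {rho.shape} does not match image grid {img.voxels.shape}"
        )
    if np.any(~np.isfinite(rho)) or np.any(rho <= 0):
        raise ValueError("every voxel needs a positive, finite density")
    conc_bq_ml = img.voxels * 1e3
    rho_kg_ml = rho * 1e-3
    dose = conc_bq_ml * constants.residence_time_s * constants.beta_energy_j / rho_kg_ml
    return DoseMap(dose, img.voxel_size)


def total_absorbed_energy_j(dose: DoseMap, density_g_ml: np.ndarray | float) -> float:
    """Σ dose × voxel mass over the grid — for energy-conservation checks."""
    rho = np.broadcast_to(np.asarray(density_g_ml, dtype=np.float64), dose.voxels.shape)
    voxel_mass_kg = rho * dose.voxel_volume_ml * 1e-3
    return float((dose.voxels * voxel_mass_kg).sum())


# ---------------------------------------------------------------------------
# compartment (partition) dose
# ---------------------------------------------------------------------------

def compartment_counts(img: ActivityImage, segs: SegmentationSet) -> dict[str, float]:
    """Image counts (∝ activity) inside the tumor and normal-liver masks."""
    validate_paired(img, segs)
    return {
        "tumor": float(img.voxels[segs.mask("tumor")].sum()),
        "liver_normal": float(img.voxels[segs.mask("liver_normal")].sum()),
    }


def compartment_masses_kg(segs: SegmentationSet, voxel_volume_ml: float,
                          constants: PhysicsConstants) -> dict[str, float]:
    """Masses of tumor / normal liver / lung from segmented volumes."""
    return {
        "tumor": float(segs.mask("tumor").sum()) * voxel_volume_ml
        * constants.soft_tissue_density_g_ml * 1e-3,
        "liver_normal": float(segs.mask("liver_normal").sum()) * voxel_volume_ml
        * constants.soft_tissue_density_g_ml * 1e-3,
        "lung": float(segs.lung_mask.sum()) * voxel_volume_ml
        * constants.lung_density_g_ml * 1e-3,
    }


def compartment_partition_dose(
    counts: dict[str, float],
    injected_activity_gbq: float,
    lsf: float,
    masses_kg: dict[str, float],
    constants: PhysicsConstants,
) -> dict[str, float]:
    """Mean dose (Gy) per compartment from activity partitioned by counts.

    Liver-directed activity ``injected × (1 − lsf)`` is split between tumor
    and normal liver in proportion to their image counts; the lungs receive
    ``injected × lsf``.  ``masses_kg`` must contain 'tumor', 'liver_normal'
    and 'lung' (use :data:`PhysicsConstants.lung_mass_kg` when no lung
    segmentation exists).
    """
    if injected_activity_gbq <= 0:
        raise ValueError("injected activity must be > 0 GBq")
    if not 0.0 <= lsf <= 1.0:
        raise ValueError(f"lung shunt fraction must lie in [0, 1], got {lsf}")
    for name in ("tumor", "liver_normal", "lung"):
        if masses_kg.get(name, 0.0) <= 0:
            raise ValueError(f"compartment mass for {name!r} must be > 0 kg")
    total_counts = counts["tumor"] + counts["liver_normal"]
    if total_counts <= 0:
        raise ValueError("liver compartment counts sum to zero — cannot partition")
    k = constants.gy_kg_per_gbq
    liver_activity = injected_activity_gbq * (1.0 - lsf)
    activity = {
        "tumor": liver_activity * counts["tumor"] / total_counts,
        "liver_normal": liver_activity * counts["liver_normal"] / total_counts,
        "lung": injected_activity_gbq * lsf,
    }
    return {name: k * a / masses_kg[name] for name, a in activity.items()}


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

def dvh(dose: DoseMap, mask: np.ndarray, compartment: str = "tumor",
        interpolate: bool = False) -> DvhSummary:
    """D2/D50/D70/Dmean of the masked voxel doses.

    Nearest-rank by default: D_x is element ⌈x/100·n⌉ (1-based) of the
    descending sort; ``interpolate=True`` uses linear interpolation between
    ranks instead.
    """
    vals = dose.voxels[mask]
    if vals.size == 0:
        raise ValueError("DVH mask is empty")
    desc = np.sort(vals)[::-1]
    n = desc.size

    def dx(x: float) -> float:
        if interpolate:
            # dose exceeded by the hottest x% of voxels = (100-x)th percentile
            return float(np.quantile(vals, 1.0 - x / 100.0, method="linear"))
        rank = max(1, math.ceil(x / 100.0 * n))
        return float(desc[rank - 1])

    return DvhSummary(
        d2=dx(2.0), d50=dx(50.0), d70=dx(70.0),
        dmean=float(vals.mean()), compartment=compartment, voxel_count=int(n),
    )


# ---------------------------------------------------------------------------
# planar geometric-mean lung shunt
# ---------------------------------------------------------------------------

def lung_shunt(
    anterior: PlanarImage,
    posterior: PlanarImage,
    lung_roi: np.ndarray,
    liver_roi: np.ndarray,
) -> ShuntResult:
    """Lung shunt fraction from anterior/posterior planar counts.

    Per organ, the geometric mean of the two views' ROI *totals* —
    GM = √(ant · post) — cancels reciprocal attenuation between the views;
    LSF = GM_lung / (GM_lung + GM_liver).
    """
    if anterior.pixels.shape != posterior.pixels.shape:
        raise ValueError(
            f"anterior {anterior.pixels.shape} and posterior {posterior.pixels.shape} "
            "planar grids differ"
        )
    if not lung_roi.any() or not liver_roi.any():
        raise ValueError("lung and liver ROIs must be non-empty")
    gm = {}
    for name, roi in (("lung", lung_roi), ("liver", liver_roi)):
        a = float(anterior.pixels[roi].sum())
        p = float(posterior.pixels[roi].sum())
        gm[name] = math.sqrt(a * p)
    denom = gm["lung"] + gm["liver"]
    if denom == 0:
        raise ValueError("zero counts in both organs — shunt fraction undefined")
    return ShuntResult(lsf=gm["lung"] / denom,
                       gm_lung_counts=gm["lung"], gm_liver_counts=gm["liver"])


def lung_safety(mean_lung_dose_gy: float, limit_gy: float = LUNG_DOSE_LIMIT_GY
                ) -> tuple[bool, float]:
    """(exceeds_limit, margin_gy): flags a mean lung dose at/above the limit."""
    return mean_lung_dose_gy >= limit_gy, limit_gy - mean_lung_dose_gy


# ---------------------------------------------------------------------------
# predicted vs actual
# ---------------------------------------------------------------------------

def _to_rows(summaries: dict[str, "DvhSummary | dict | float"]) -> pd.DataFrame:
    rows = []
    for comp, s in summaries.items():
        if isinstance(s, DvhSummary):
            stats = s.as_dict()
        elif isinstance(s, dict):
            stats = s
        else:
            stats = {"dmean": float(s)}
        for stat, value in stats.items():
            rows.append({"compartment": comp, "statistic": stat, "value": float(value)})
    return pd.DataFrame(rows)


def predicted_vs_actual(
    predicted: dict[str, "DvhSummary | dict | float"],
    actual: dict[str, "DvhSummary | dict | float"],
) -> pd.DataFrame:
    """Paired comparison table of predicted vs measured doses.

    Inputs map compartment name → DvhSummary, dict of statistics, or a bare
    mean dose.  Compartment/statistic sets must match; percent difference is
    (actual − predicted)/predicted × 100.
    """
    pred = _to_rows(predicted).rename(columns={"value": "predicted_gy"})
    act = _to_rows(actual).rename(columns={"value": "actual_gy"})
    merged = pred.merge(act, on=["compartment", "statistic"], how="outer", indicator=True)
    missing = merged[merged["_merge"] != "both"]
    if len(missing):
        pairs = sorted(zip(missing["compartment"], missing["statistic"]))
        raise ValueError(f"compartment/statistic mismatch between tables: {pairs}")
    merged = merged.drop(columns="_merge")
    merged["diff_gy"] = merged["actual_gy"] - merged["predicted_gy"]
    merged["pct_diff"] = 100.0 * merged["diff_gy"] / merged["predicted_gy"]
    return merged
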