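"""Study orchestration: simulate → VOI → IQ metrics → dosimetry → comparisons.

A :class:`StudyConfig` pins everything a run depends on — phantom, noise
model, the duration × iteration factorial, replicate count, VOI set, physics
constants and one master seed — so a run is reproducible end to end and the
simulated "cohort" of replicates stands in for a patient cohort.

All randomness flows from the master seed through per-condition child seeds;
the same config therefore yields bit-identical images, tables and manifest
checksums on every run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dosimetry, metrics, voi
from .constants import PhysicsConstants
from .image_io import write_image, write_segmentation
from .phantom import (
    DEFAULT_DURATIONS_MIN,
    DEFAULT_ITERATIONS,
    AcquisitionCondition,
    NoiseModel,
    PhantomSpec,
    apply_psf,
    build_ground_truth,
    condition_seed_sequence,
    default_phantom_spec,
    maa_variant,
    project_roi,
    simulate_acquisition,
    simulate_planar_pair,
)
from .voi import VoiSpec, default_voi_specs

log = logging.getLogger("y90pet")

IQ_METRICS = ["snr_peak", "snr_mean", "cov", "lbr"]
DOSE_METRICS = ["tumor_d2", "tumor_d50", "tumor_d70", "tumor_dmean",
                "liver_dmean", "lung_dmean"]


class PipelineSelfCheckError(RuntimeError):
    """An internal physics invariant failed during a pipeline run."""


@dataclass
class StudyConfig:
    phantom: PhantomSpec = field(default_factory=default_phantom_spec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    durations_min: tuple[float, ...] = DEFAULT_DURATIONS_MIN
    iterations: tuple[int, ...] = DEFAULT_ITERATIONS
    replicates: int = 17
    vois: list[VoiSpec] | None = None  # None → default placements for the phantom
    constants: PhysicsConstants = field(default_factory=PhysicsConstants)
    reference_duration_min: float = 20.0
    reference_iterations: int = 2
    injected_activity_gbq: float | None = None  # None → derived from liver+lung truth
    maa_tumor_scale: float = 1.09
    maa_lung_scale: float = 2.0
    planar_counts_per_kbq: float = 1.0
    planar_poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.durations_min or not self.iterations:
            raise ValueError("condition grid must be non-empty")
        if self.reference_duration_min not in self.durations_min or \
                self.reference_iterations not in self.iterations:
            raise ValueError(
                f"reference condition ({self.reference_duration_min} min, "
                f"{self.reference_iterations} it) not in the condition grid"
            )
        if self.replicates < 0:
            raise ValueError("replicate count must be >= 0")

    @property
    def conditions(self) -> list[tuple[float, int]]:
        return [(d, i) for d in self.durations_min for i in self.iterations]

    def voi_specs(self) -> list[VoiSpec]:
        return self.vois if self.vois is not None else default_voi_specs(self.phantom)

    # -- (de)serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["phantom"] = PhantomSpec.from_dict(d["phantom"])
        d["noise"] = NoiseModel(
            counts_per_kbqml_min=d["noise"]["counts_per_kbqml_min"],
            iteration_noise_gain={int(k): v for k, v in
                                  d["noise"]["iteration_noise_gain"].items()},
        )
        d["constants"] = PhysicsConstants(**d["constants"])
        if d.get("vois") is not None:
            d["vois"] = [VoiSpec(tuple(v["center_vox"]), v["radius_mm"], v["role"])
                         for v in d["vois"]]
        d["durations_min"] = tuple(d["durations_min"])
        d["iterations"] = tuple(d["iterations"])
        return cls(**d)


def default_config(seed: int = 0, **overrides) -> StudyConfig:
    return StudyConfig(phantom=default_phantom_spec(seed=seed), seed=seed, **overrides)


def derived_injected_activity_gbq(config: StudyConfig, truth, segs) -> float:
    """Injected activity implied by the phantom: liver + lung truth activity.

    The phantom preserves clinical concentration and dose scales at reduced
    organ volumes, so the commensurate administered activity is the one the
    phantom actually contains in its perfused compartments.
    """
    if config.injected_activity_gbq is not None:
        return config.injected_activity_gbq
    mask = segs.whole_liver_mask | segs.lung_mask
    return float(truth.voxels[mask].sum() * truth.voxel_volume_ml) / 1e6  # kBq → GBq


# ---------------------------------------------------------------------------
# simulate to disk
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_simulate(config: StudyConfig, out_dir, force: bool = False) -> dict:
    """Write the full condition × replicate image tree plus a manifest.

    Refuses to write over prior output unless ``force``.  With
    ``replicates=0`` only the manifest is written.  File bytes are produced
    deterministically from the master seed, so re-running yields identical
    checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prior = list(out.glob("*.nii.gz")) + list(out.glob("manifest.json"))
    if prior and not force:
        raise FileExistsError(
            f"{out} already holds {len(prior)} output file(s); pass force=True to overwrite"
        )
    truth, segs = build_ground_truth(config.phantom)
    blurred = apply_psf(truth, config.phantom.psf_fwhm_mm)
    files: dict[str, dict] = {}
    if config.replicates > 0:
        write_image(truth, out / "truth.nii.gz")
        write_segmentation(segs, out / "labels.nii.gz")
        files["truth.nii.gz"] = {"sha256": _sha256(out / "truth.nii.gz")}
        files["labels.nii.gz"] = {"sha256": _sha256(out / "labels.nii.gz")}
    for rep in range(config.replicates):
        for dur, its in config.conditions:
            cond = AcquisitionCondition(dur, its, rep)
            img = simulate_acquisition(truth, cond, config.noise,
                                       config.phantom.psf_fwhm_mm,
                                       seed=config.seed, blurred=blurred)
            name = f"rep{rep:02d}_dur{dur:g}min_it{its}.nii.gz"
            write_image(img, out / name)
            files[name] = {
                "sha256": _sha256(out / name),
                "seed_state": condition_seed_sequence(config.seed, cond).entropy,
            }
    manifest = {
        "seed": config.seed,
        "replicates": config.replicates,
        "conditions": [[d, i] for d, i in config.conditions],
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log.info("simulate: wrote %d files to %s", len(files), out)
    return manifest


# ---------------------------------------------------------------------------
# in-memory analysis stages
# ---------------------------------------------------------------------------

def _study_tables(config: StudyConfig, want_dose: bool = True,
                  want_iq: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One pass over the cohort: IQ rows and (optionally) dose rows."""
    truth, segs = build_ground_truth(config.phantom)
    blurred = apply_psf(truth, config.phantom.psf_fwhm_mm)
    lesion_mask = bg_masks = None
    if want_iq:
        lesion_mask, bg_masks = voi.build_voi_masks(
            config.voi_specs(), truth.voxels.shape, truth.voxel_size
        )
    tumor_mask = segs.mask("tumor")
    liver_mask = segs.mask("liver_normal")
    lung_mask = segs.lung_mask
    rho = dosimetry.density_map(segs, config.constants)

    iq_rows, dose_rows = [], []
    for rep in range(config.replicates):
        for dur, its in config.conditions:
            cond = AcquisitionCondition(dur, its, rep)
            img = simulate_acquisition(truth, cond, config.noise,
                                       config.phantom.psf_fwhm_mm,
                                       seed=config.seed, blurred=blurred)
            if want_iq:
                report = voi.extract_report(img, lesion_mask, bg_masks, cond)
                iq_rows.append(metrics.compute_iq(report))
            if want_dose:
                dose = dosimetry.voxel_ldm_dose(img, config.constants, rho)
                tumor_dvh = dosimetry.dvh(dose, tumor_mask, "tumor")
                dose_rows.append({
                    "replicate": rep, "duration_min": dur, "iterations": its,
                    "tumor_d2": tumor_dvh.d2, "tumor_d50": tumor_dvh.d50,
                    "tumor_d70": tumor_dvh.d70, "tumor_dmean": tumor_dvh.dmean,
                    "liver_dmean": float(dose.voxels[liver_mask].mean()),
                    "lung_dmean": float(dose.voxels[lung_mask].mean()),
                })
    return metrics.iq_frame(iq_rows), pd.DataFrame(dose_rows)


def run_iq(config: StudyConfig) -> pd.DataFrame:
    """Tidy IQ-metric table: one row per (replicate, duration, iterations)."""
    t0 = time.perf_counter()
    df, _ = _study_tables(config, want_dose=False)
    log.info("iq: %d rows in %.1f s", len(df), time.perf_counter() - t0)
    return df


def run_shunt(config: StudyConfig) -> dosimetry.ShuntResult:
    """Lung shunt fraction from the pre-treatment (MAA surrogate) planars."""
    maa_truth, segs = build_ground_truth(
        maa_variant(config.phantom, config.maa_tumor_scale, config.maa_lung_scale)
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    ant, post = simulate_planar_pair(
        maa_truth, segs,
        counts_per_kbq=config.planar_counts_per_kbq,
        poisson=config.planar_poisson, rng=rng,
    )
    return dosimetry.lung_shunt(
        ant, post,
        project_roi(segs, "lung_left", "lung_right"),
        project_roi(segs, "tumor", "liver_normal"),
    )


def run_dose(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame, dosimetry.ShuntResult]:
    """(per-condition dose table, predicted-vs-actual table, shunt result).

    Predicted doses come from the partition model on the MAA surrogate
    phantom (counts per compartment, planar shunt fraction, administered
    activity); actual doses are replicate-averaged LDM voxel doses of the
    simulated reference-condition PET images.
    """
    t0 = time.perf_counter()
    _, dose_df = _study_tables(config, want_dose=True, want_iq=False)

    truth, segs = build_ground_truth(config.phantom)
    injected = derived_injected_activity_gbq(config, truth, segs)
    shunt = run_shunt(config)
    maa_truth, _ = build_ground_truth(
        maa_variant(config.phantom, config.maa_tumor_scale, config.maa_lung_scale)
    )
    maa_img = apply_psf(maa_truth, config.phantom.psf_fwhm_mm)
    counts = dosimetry.compartment_counts(maa_img, segs)
    masses = dosimetry.compartment_masses_kg(segs, truth.voxel_volume_ml, config.constants)
    predicted = dosimetry.compartment_partition_dose(
        counts, injected, shunt.lsf, masses, config.constants
    )

    ref = dose_df[(dose_df["duration_min"] == config.reference_duration_min)
                  & (dose_df["iterations"] == config.reference_iterations)]
    actual = {
        "tumor": float(ref["tumor_dmean"].mean()),
        "liver_normal": float(ref["liver_dmean"].mean()),
        "lung": float(ref["lung_dmean"].mean()),
    }
    comparison = dosimetry.predicted_vs_actual(predicted, actual)
    log.info("dose: %d rows in %.1f s (lsf=%.4f, injected=%.3f GBq)",
             len(dose_df), time.perf_counter() - t0, shunt.lsf, injected)
    return dose_df, comparison, shunt


def run_compare(iq_df: pd.DataFrame, dose_df: pd.DataFrame | None,
                config: StudyConfig) -> pd.DataFrame:
    """Wilcoxon comparison matrix over the condition grid for every metric.

    The canonical pair lists (six duration pairs, three iteration pairs) are
    restricted to conditions the config actually simulates, so reduced grids
    still produce a (smaller) comparison table.
    """
    from .stats import DURATION_PAIRS, ITERATION_PAIRS, condition_grid_report

    duration_pairs = tuple(
        p for p in DURATION_PAIRS
        if p[0] in config.durations_min and p[1] in config.durations_min
    )
    iteration_pairs = tuple(
        p for p in ITERATION_PAIRS
        if p[0] in config.iterations and p[1] in config.iterations
    )
    kwargs = dict(
        duration_pairs=duration_pairs,
        iteration_pairs=iteration_pairs,
        reference_duration=config.reference_duration_min,
        reference_iterations=config.reference_iterations,
    )
    frames = [condition_grid_report(iq_df, IQ_METRICS, **kwargs)]
    if dose_df is not None and len(dose_df):
        frames.append(condition_grid_report(dose_df, DOSE_METRICS, **kwargs))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# self-checks
# ---------------------------------------------------------------------------

def self_check(config: StudyConfig) -> dict[str, float]:
    """Physics invariants any run must satisfy; raises on failure.

    Energy conservation: Σ(voxel dose × voxel mass) of the noiseless truth
    must equal total imaged activity × the derived J/GBq constant to 1e-6
    relative.  DVH ordering D2 ≥ D50 ≥ D70 is asserted on the truth dose map.
    """
    truth, segs = build_ground_truth(config.phantom)
    rho = dosimetry.density_map(segs, config.constants)
    dose = dosimetry.voxel_ldm_dose(truth, config.constants, rho)
    energy = dosimetry.total_absorbed_energy_j(dose, rho)
    expected = truth.total_activity_kbq * 1e-6 * config.constants.gy_kg_per_gbq
    rel = abs(energy - expected) / expected
    if rel > 1e-6:
        raise PipelineSelfCheckError(
            f"energy conservation violated: rel. error {rel:.2e} (Σ dose·mass "
            f"{energy:.6g} J vs activity×constant {expected:.6g} J)"
        )
    d = dosimetry.dvh(dose, segs.mask("tumor"))  # DvhSummary validates ordering
    return {"energy_rel_error": rel, "truth_tumor_dmean_gy": d.dmean}


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_full(config: StudyConfig, out_dir, skip_dose: bool = False,
             write_images: bool = False, force: bool = False) -> dict:
    """One command: simulate the cohort, extract every table, write a bundle.

    Outputs under ``out_dir``: ``iq_metrics.csv``, ``dose_metrics.csv``,
    ``predicted_vs_actual.csv``, ``shunt.json``, ``comparisons.csv``,
    boxplot figures per IQ metric and a ``summary.json``.  Raises (non-zero
    CLI exit) if any stage or internal self-check fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    results: dict = {"out_dir": str(out)}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self
            def __exit__(self, exc_type, exc, tb):
                stages[name] = time.perf_counter() - self.t0
                log.info("stage %s: %s in %.1f s", name,
                         "FAILED" if exc else "done", stages[name])
                return False
        return _T()

    with stage("self_check"):
        results["self_check"] = self_check(config)
    if write_images:
        with stage("simulate"):
            run_simulate(config, out / "images", force=force)
    with stage("analyze"):
        iq_df, dose_df = _study_tables(config, want_dose=not skip_dose)
        iq_df.to_csv(out / "iq_metrics.csv", index=False)
    if not skip_dose:
        with stage("dose"):
            truth, segs = build_ground_truth(config.phantom)
            injected = derived_injected_activity_gbq(config, truth, segs)
            shunt = run_shunt(config)
            maa_truth, _ = build_ground_truth(
                maa_variant(config.phantom, config.maa_tumor_scale, config.maa_lung_scale)
            )
            maa_img = apply_psf(maa_truth, config.phantom.psf_fwhm_mm)
            counts = dosimetry.compartment_counts(maa_img, segs)
            masses = dosimetry.compartment_masses_kg(
                segs, truth.voxel_volume_ml, config.constants)
            predicted = dosimetry.compartment_partition_dose(
                counts, injected, shunt.lsf, masses, config.constants)
            ref = dose_df[(dose_df["duration_min"] == config.reference_duration_min)
                          & (dose_df["iterations"] == config.reference_iterations)]
            actual = {
                "tumor": float(ref["tumor_dmean"].mean()),
                "liver_normal": float(ref["liver_dmean"].mean()),
                "lung": float(ref["lung_dmean"].mean()),
            }
            comparison = dosimetry.predicted_vs_actual(predicted, actual)
            dose_df.to_csv(out / "dose_metrics.csv", index=False)
            comparison.to_csv(out / "predicted_vs_actual.csv", index=False)
            exceeded, margin = dosimetry.lung_safety(actual["lung"])
            (out / "shunt.json").write_text(json.dumps({
                "lsf": shunt.lsf, "gm_lung_counts": shunt.gm_lung_counts,
                "gm_liver_counts": shunt.gm_liver_counts,
                "injected_activity_gbq": injected,
                "mean_lung_dose_gy": actual["lung"],
                "lung_limit_exceeded": bool(exceeded),
                "lung_margin_gy": margin,
            }, indent=1))
            results["shunt"] = shunt
            results["predicted_vs_actual"] = comparison
    with stage("compare"):
        comparisons = run_compare(iq_df, None if skip_dose else dose_df, config)
        comparisons.to_csv(out / "comparisons.csv", index=False)
    with stage("figures"):
        from .stats import plot_condition_boxplots
        for m in IQ_METRICS:
            plot_condition_boxplots(iq_df, m, out / f"boxplot_{m}.png",
                                    reference_iterations=config.reference_iterations)
    (out / "summary.json").write_text(json.dumps({
        "seed": config.seed,
        "replicates": config.replicates,
        "n_conditions": len(config.conditions),
        "stage_seconds": stages,
        "self_check": results["self_check"],
    }, indent=1))
    results["iq"] = iq_df
    results["dose"] = None if skip_dose else dose_df
    results["comparisons"] = comparisons
    results["stage_seconds"] = stages
    return results
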