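"""Image-quality statistics from VOI reports.

Four dimensionless metrics, all ratios of VOI statistics so they are
invariant under rescaling the whole image by a positive constant:

* ``SNR_peak = (lesion_peak − bg_mean) / bg_sd``
* ``SNR_mean = (lesion_mean − bg_mean) / bg_sd``
* ``COV      = bg_sd / bg_mean``           (background-noise surrogate)
* ``LBR      = lesion_max / bg_mean``      (lesion-to-background ratio)

A zero background SD (noiseless image) or zero background mean makes the
corresponding metric undefined; that is an explicit error rather than a NaN
silently propagating into summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .phantom import AcquisitionCondition
from .voi import VoiReport


@dataclass(frozen=True)
class IqResult:
    snr_peak: float
    snr_mean: float
    cov: float
    lbr: float
    condition: AcquisitionCondition


def _require_sd(report: VoiReport) -> None:
    if report.bg_sd <= 0:
        raise ValueError("background SD is zero (noiseless input): SNR is undefined")


def _require_mean(report: VoiReport) -> None:
    if report.bg_mean <= 0:
        raise ValueError("background mean is zero: COV/LBR are undefined")


def snr_peak(report: VoiReport) -> float:
    _require_sd(report)
    return (report.lesion_peak - report.bg_mean) / report.bg_sd


def snr_mean(report: VoiReport) -> float:
    _require_sd(report)
    return (report.lesion_mean - report.bg_mean) / report.bg_sd


def cov(report: VoiReport) -> float:
    _require_mean(report)
    return report.bg_sd / report.bg_mean


def lbr(report: VoiReport) -> float:
    _require_mean(report)
    return report.lesion_max / report.bg_mean


def compute_iq(report: VoiReport) -> IqResult:
    """All four metrics of one condition; aborts if any is undefined."""
    return IqResult(
        snr_peak=snr_peak(report),
        snr_mean=snr_mean(report),
        cov=cov(report),
        lbr=lbr(report),
        condition=report.condition,
    )


def iq_frame(results: list[IqResult]) -> pd.DataFrame:
    """Tidy table: one row per (replicate, duration, iterations)."""
    return pd.DataFrame(
        {
            "replicate": [r.condition.replicate_index for r in results],
            "duration_min": [r.condition.duration_min for r in results],
            "iterations": [r.condition.iterations for r in results],
            "snr_peak": [r.snr_peak for r in results],
            "snr_mean": [r.snr_mean for r in results],
            "cov": [r.cov for r in results],
            "lbr": [r.lbr for r in results],
        }
    )
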