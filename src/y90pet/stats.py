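"""Paired nonparametric comparisons and boxplot summaries.

The study's inferential tool is the two-sided Wilcoxon signed-rank test on
paired per-subject (here: per-replicate) metrics.  For small samples the
p-value is *exact*: the null distribution of the positive-rank sum W⁺ over
all 2ⁿ equiprobable sign patterns is built by dynamic programming over the
(midrank-tied) ranks, which is numerically identical to brute-force
enumeration but O(n·Σr) instead of O(2ⁿ).  Ties in |d| get midranks; zero
differences are dropped by default (the classical Wilcoxon convention;
Pratt's method is available behind a flag).  Above ``exact_threshold`` the
normal approximation with tie correction is used.

No multiple-testing correction is applied anywhere: comparisons are reported
pair by pair, each at the 0.05 level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class PairedSample:
    labels: tuple
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1 or a.size < 1:
            raise ValueError("paired sample needs two equal-length 1-D arrays, n >= 1")
        if len(self.labels) != a.size:
            raise ValueError("labels length must match the sample length")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired sample values must be finite")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float          # W = min(W+, W-)
    p_value: float
    n_used: int               # pairs remaining after zero handling
    method: str               # "exact" | "normal"
    all_zero: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """P(min(W⁺, W⁻) ≤ observed) under the 2ⁿ sign-flip null.

    DP over doubled midranks (integers even with .5 ties): ``counts[s]`` is
    the number of sign patterns with doubled rank sum s.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    s2 = int(r2.sum())
    counts = np.zeros(s2 + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[: s2 + 1 - r]
    w2 = int(round(2.0 * min(w_plus, r2.sum() / 2.0 - w_plus)))
    if s2 - w2 <= w2:
        return 1.0
    total = 2.0 ** len(r2)
    return float((counts[: w2 + 1].sum() + counts[s2 - w2:].sum()) / total)


def wilcoxon_signed_rank(
    sample: PairedSample,
    zero_method: str = "wilcox",
    exact_threshold: int = 25,
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Differences d = b − a; zero differences are dropped (``zero_method=
    'wilcox'``) or handled by Pratt's method (``'pratt'``, normal
    approximation).  If every difference is zero the result is p = 1 with a
    warning flag.  Exact enumeration p for n ≤ ``exact_threshold``; a cohort
    of 17 subjects falls in the exact regime.
    """
    d = sample.values_b - sample.values_a
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1 by convention")
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", all_zero=True)

    if zero_method == "pratt":
        stat, p = sps.wilcoxon(sample.values_b, sample.values_a,
                               zero_method="pratt", mode="approx")
        n = int(np.count_nonzero(d != 0))
        return WilcoxonResult(float(stat), float(p), n, "normal")

    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= exact_threshold:
        return WilcoxonResult(w, _exact_p(ranks, w_plus), n, "exact")

    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w, p, n, "normal")


# ---------------------------------------------------------------------------
# boxplot summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    mean: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles must bracket the median")


def summarize(values) -> BoxplotSummary:
    """Boxplot statistics with Tukey 1.5·IQR whiskers clipped to the data.

    Quartiles use linear interpolation between closest ranks (the numpy
    default) — IQRs depend on this convention, so it is pinned here.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("cannot summarize an empty sample")
    if not np.all(np.isfinite(v)):
        raise ValueError("summary input must be finite")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(np.sort(v[(v < lo_fence) | (v > hi_fence)]).tolist())
    return BoxplotSummary(
        median=float(med), mean=float(v.mean()), q1=float(q1), q3=float(q3),
        iqr=float(iqr), whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# condition-grid comparisons
# ---------------------------------------------------------------------------

#: Duration pairs compared at the reference iteration number.
DURATION_PAIRS = ((20.0, 15.0), (15.0, 10.0), (10.0, 5.0), (5.0, 1.0), (20.0, 5.0), (20.0, 1.0))
#: Iteration pairs compared at the reference duration.
ITERATION_PAIRS = ((2, 4), (2, 6), (2, 8))


def _paired_values(df: pd.DataFrame, metric: str, duration: float, iterations: int
                   ) -> pd.Series:
    cell = df[(df["duration_min"] == duration) & (df["iterations"] == iterations)]
    if cell.empty:
        raise ValueError(f"missing condition (duration={duration} min, iterations={iterations})")
    return cell.sort_values("replicate").set_index("replicate")[metric]


def condition_grid_report(
    df: pd.DataFrame,
    metrics: list[str],
    duration_pairs=DURATION_PAIRS,
    iteration_pairs=ITERATION_PAIRS,
    reference_duration: float = 20.0,
    reference_iterations: int = 2,
) -> pd.DataFrame:
    """Pairwise Wilcoxon tests over the factorial of study conditions.

    For each metric: the six duration pairs at the reference iteration
    number, plus the reference duration's iteration pairs — one tidy row per
    (metric, pair) with the statistic, two-sided p and 0.05 significance.
    """
    rows = []
    for metric in metrics:
        if metric not in df.columns:
            raise ValueError(f"metric column {metric!r} not in table")
        for a, b in duration_pairs:
            va = _paired_values(df, metric, a, reference_iterations)
            vb = _paired_values(df, metric, b, reference_iterations)
            common = va.index.intersection(vb.index)
            res = wilcoxon_signed_rank(
                PairedSample(tuple(common), va[common].values, vb[common].values)
            )
            rows.append({
                "metric": metric, "comparison": "duration",
                "pair": f"{a:g} vs {b:g} min", "n": res.n_used,
                "statistic": res.statistic, "p_value": res.p_value,
                "significant": res.significant,
            })
        for a, b in iteration_pairs:
            va = _paired_values(df, metric, reference_duration, a)
            vb = _paired_values(df, metric, reference_duration, b)
            common = va.index.intersection(vb.index)
            res = wilcoxon_signed_rank(
                PairedSample(tuple(common), va[common].values, vb[common].values)
            )
            rows.append({
                "metric": metric, "comparison": "iterations",
                "pair": f"{a} vs {b} it", "n": res.n_used,
                "statistic": res.statistic, "p_value": res.p_value,
                "significant": res.significant,
            })
    return pd.DataFrame(rows)


def plot_condition_boxplots(df: pd.DataFrame, metric: str, path,
                            reference_iterations: int = 2) -> None:
    """Boxplot of a metric across scan durations (median line, mean marker,
    1.5·IQR whiskers, outlier fliers)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = df[df["iterations"] == reference_iterations]
    durations = sorted(sub["duration_min"].unique(), reverse=True)
    data = [sub[sub["duration_min"] == d][metric].values for d in durations]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=[f"{d:g}" for d in durations], whis=1.5,
               showmeans=True, meanprops={"marker": "o", "markerfacecolor": "gold"})
    ax.set_xlabel("scan duration (min)")
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
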