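"""Windowed density tracks, Z-scores, region assignment, and changepoints.

Feature densities are computed in sliding windows (default 10 Mb, step 1 Mb)
by counting feature midpoints per half-open window; Z-scores standardize a
track with the sample (n-1) standard deviation. Mean-shift changepoints are
found by binary segmentation under a Gaussian mean-change model with a
BIC-style penalty beta = 2 log n; the noise variance is estimated once from
first differences of the series. Region-wise feature comparisons use Welch's
t-test and gradients along the centromere-telomere axis use Spearman rank
correlation.
"""
from __future__ import annotations

import logging
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import RegionTable, SegmentationResult, WindowTrack

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000_000
DEFAULT_STEP = 1_000_000


def windowed_density(
    midpoints: Sequence[float],
    chrom_length: int,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    chrom: str = ".",
) -> WindowTrack:
    """Feature density per Mb in sliding windows.

    A feature is counted in window w iff its midpoint falls in
    [w_start, w_start + window) -- half-open, so a midpoint on a boundary
    belongs to the right-hand window only.
    """
    if window > chrom_length:
        log.warning("window (%d) > chromosome length (%d); using one window",
                    window, chrom_length)
        window = chrom_length
        starts = np.array([0])
    else:
        n_windows = (chrom_length - window) // step + 1
        starts = np.arange(n_windows) * step
    mids = np.asarray(midpoints, dtype=float)
    values = np.empty(len(starts))
    for i, s in enumerate(starts):
        values[i] = np.count_nonzero((mids >= s) & (mids < s + window))
    values /= window / 1e6
    return WindowTrack(chrom=chrom, window=window, step=step, starts=starts,
                       values=values)


def zscore(track: WindowTrack) -> WindowTrack:
    """Standardize track values with the sample (n-1) SD; an SD of zero
    yields all-zero scores."""
    if track.n_windows < 2:
        raise ValueError("need at least 2 windows")
    v = track.values
    sd = v.std(ddof=1)
    track.zscores = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
    return track


def assign_region(position: float, regions: RegionTable) -> str:
    """Region containing a position; membership is [start, end) except the
    last region, which is right-closed."""
    if position < 0 or position > regions.length:
        raise ValueError(f"position {position} outside chromosome [0, {regions.length}]")
    for i, (name, s, e) in enumerate(regions.regions):
        if s <= position < e or (i == len(regions.regions) - 1 and position == e):
            return name
    raise AssertionError("unreachable: regions tile the chromosome")


def _rss(prefix: np.ndarray, prefix2: np.ndarray, lo: int, hi: int) -> float:
    """Residual sum of squares of x[lo:hi] around its mean, via prefix sums."""
    n = hi - lo
    s = prefix[hi] - prefix[lo]
    s2 = prefix2[hi] - prefix2[lo]
    return s2 - s * s / n


def best_single_split(
    x: np.ndarray, lo: int = 0, hi: Optional[int] = None, min_size: int = 2
) -> tuple[Optional[int], float]:
    """Exhaustive best split of x[lo:hi] under a two-mean model.

    Returns (index of last point of the left segment, RSS gain); the index
    is None when no admissible split exists.
    """
    if hi is None:
        hi = len(x)
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])
    rss0 = _rss(prefix, prefix2, lo, hi)
    best_k, best_gain = None, 0.0
    for k in range(lo + min_size - 1, hi - min_size):
        gain = rss0 - _rss(prefix, prefix2, lo, k + 1) - _rss(prefix, prefix2, k + 1, hi)
        if gain > best_gain:
            best_k, best_gain = k, gain
    return best_k, best_gain


def binary_segmentation(
    series: Sequence[float],
    step_bp: int = DEFAULT_STEP,
    min_size: int = 2,
    penalty: str = "BIC",
) -> SegmentationResult:
    """Recursive mean-shift changepoint detection.

    At each stage the split minimizing the residual sum of squares under a
    two-mean Gaussian model is accepted iff twice the log-likelihood gain
    exceeds beta = 2 log n (n = series length); the noise variance is
    estimated once from first differences, var(diff)/2. Recursion continues
    on both sides. Changepoint indices mark the last window of each left
    segment. A zero-variance series yields no changepoints.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 points")
    if penalty != "BIC":
        raise ValueError("only the BIC penalty is implemented")
    diffs = np.diff(x)
    sigma2 = float(np.var(diffs)) / 2.0
    beta = 2.0 * np.log(n)
    changepoints: list[int] = []

    if sigma2 > 0:
        stack = [(0, n)]
        while stack:
            lo, hi = stack.pop()
            if hi - lo < 2 * min_size:
                continue
            k, gain = best_single_split(x, lo, hi, min_size)
            if k is not None and gain / sigma2 > beta:
                changepoints.append(k)
                stack.append((lo, k + 1))
                stack.append((k + 1, hi))
    changepoints.sort()

    bounds = [0] + [k + 1 for k in changepoints] + [n]
    means = [float(x[a:b].mean()) for a, b in zip(bounds, bounds[1:])]
    return SegmentationResult(
        changepoints=changepoints,
        changepoint_bp=[(k + 1) * step_bp for k in changepoints],
        segment_means=means,
        penalty=beta,
    )


def region_feature_stats(
    features: pd.DataFrame,
    positions: pd.Series,
    regions: RegionTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region summaries and pairwise Welch t-tests per feature.

    ``features`` is indexed by gene id; ``positions`` gives each gene's
    midpoint (bp). Regions with fewer than 2 genes are summarized but
    excluded from testing.
    """
    region_of = positions.map(lambda p: assign_region(p, regions))
    summaries = []
    tests = []
    for feat in features.columns:
        groups = {}
        for name in regions.names:
            v = features.loc[region_of[region_of == name].index, feat].dropna().to_numpy()
            groups[name] = v
            q = np.percentile(v, [25, 50, 75]) if len(v) else [np.nan] * 3
            summaries.append(
                {"feature": feat, "region": name, "n": len(v),
                 "mean": v.mean() if len(v) else np.nan,
                 "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                 "q1": q[0], "median": q[1], "q3": q[2]}
            )
        for a, b in combinations(regions.names, 2):
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                log.info("Welch test skipped for %s: region with n<2", feat)
                continue
            t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
            tests.append({"feature": feat, "region_a": a, "region_b": b,
                          "t": float(t), "p": float(p)})
    return pd.DataFrame(summaries), pd.DataFrame(tests)


def region_density(
    midpoints: Sequence[float], regions: RegionTable
) -> pd.DataFrame:
    """Features per Mb in each named region (midpoint assignment)."""
    rows = []
    mids = np.asarray(midpoints, dtype=float)
    for name, s, e in regions.regions:
        n = int(np.count_nonzero((mids >= s) & (mids < e)))
        rows.append({"region": name, "n": n, "mb": (e - s) / 1e6,
                     "density_per_mb": n / ((e - s) / 1e6)})
    return pd.DataFrame(rows)


def spearman_gradient(
    values: Sequence[float], distances: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (ties mid-ranked, t-approximation p-value)
    between a feature and the distance to the centromere."""
    v = np.asarray(values, dtype=float)
    d = np.asarray(distances, dtype=float)
    if len(v) < 4:
        raise ValueError("need n >= 4")
    if v.std() == 0 or d.std() == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(v, d)
    return float(rho), float(p)


def distance_to_centromere(
    positions: Sequence[float], regions: RegionTable, centromere_region: str = "C"
) -> np.ndarray:
    """Distance from each position to the midpoint of the centromeric region."""
    for name, s, e in regions.regions:
        if name == centromere_region:
            mid = (s + e) / 2.0
            return np.abs(np.asarray(positions, dtype=float) - mid)
    raise ValueError(f"no region named {centromere_region!r}")


def distribution_fit_chi2(
    observed_midpoints: Sequence[float],
    reference_midpoints: Sequence[float],
    chrom_length: int,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> tuple[float, int]:
    """Goodness-of-fit chi-square of one feature's windowed counts against
    the distribution of a reference feature (e.g. expressed vs predicted
    genes), over the sliding windows. Windows with zero expected count are
    dropped. Returns (chi2, degrees of freedom)."""
    obs = windowed_density(observed_midpoints, chrom_length, window, step).values
    ref = windowed_density(reference_midpoints, chrom_length, window, step).values
    obs_counts = obs * window / 1e6
    exp_counts = ref * window / 1e6
    keep = exp_counts > 0
    obs_counts, exp_counts = obs_counts[keep], exp_counts[keep]
    exp_counts = exp_counts * obs_counts.sum() / exp_counts.sum()
    chi2 = float(((obs_counts - exp_counts) ** 2 / exp_counts).sum())
    return chi2, int(keep.sum() - 1)
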