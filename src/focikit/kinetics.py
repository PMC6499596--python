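"""Focus-resolution kinetics: tracking, classification, and population statistics.

Per-cell focus counts at two or more post-irradiation timepoints are turned
into resolution fractions, fast-resolver calls (strictly more than 85% of
foci gone between the first and second observation), smoothed normalized
count histograms, and the comparison statistics used to contrast cell
populations (pooled-variance Student t-tests, Pearson correlation of
nuclear intensity vs focus count, and a median-matching resolution speed
ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

FAST_RESOLVER_THRESHOLD = 0.85


# ---------------------------------------------------------------------------
# cross-timepoint matching
# ---------------------------------------------------------------------------

def match_cells(records_t0: pd.DataFrame, records_t1: pd.DataFrame,
                max_displacement_px: float, method: str = "mutual"
                ) -> pd.DataFrame:
    """Match nuclei across two timepoints of the same field by centroid.

    'mutual' keeps mutual-nearest-neighbour pairs closer than
    ``max_displacement_px``; 'optimal' solves the globally optimal
    assignment (Hungarian) under the same displacement gate, as a
    verification mode. Unmatched nuclei are simply absent from the output.

    Returns columns (label_t0, label_t1, displacement_px).
    """
    cols = ["label_t0", "label_t1", "displacement_px"]
    if records_t0.empty or records_t1.empty:
        return pd.DataFrame(columns=cols)
    p0 = records_t0[["centroid_row", "centroid_col"]].to_numpy(float)
    p1 = records_t1[["centroid_row", "centroid_col"]].to_numpy(float)
    l0 = records_t0["label"].to_numpy(int)
    l1 = records_t1["label"].to_numpy(int)

    pairs: list[tuple[int, int, float]] = []
    if method == "mutual":
        t0, t1 = cKDTree(p0), cKDTree(p1)
        d01, j01 = t1.query(p0)
        d10, j10 = t0.query(p1)
        for i, (d, j) in enumerate(zip(d01, j01)):
            if d <= max_displacement_px and j10[j] == i:
                pairs.append((l0[i], l1[j], float(d)))
    elif method == "optimal":
        dm = np.hypot(p0[:, None, 0] - p1[None, :, 0],
                      p0[:, None, 1] - p1[None, :, 1])
        cost = np.where(dm <= max_displacement_px, dm, 1e9)
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            if dm[i, j] <= max_displacement_px:
                pairs.append((l0[i], l1[j], float(dm[i, j])))
    else:
        raise ValueError("method must be 'mutual' or 'optimal'")
    return pd.DataFrame(pairs, columns=cols)


def resolution_fraction(count_t0, count_t1):
    """Fraction of foci resolved between the two observations.

    1 - count_t1 / count_t0; NaN (undefined) where count_t0 == 0; may be
    negative when counts rise. Accepts scalars or arrays.
    """
    c0 = np.asarray(count_t0, dtype=float)
    c1 = np.asarray(count_t1, dtype=float)
    if (c0 < 0).any() or (c1 < 0).any():
        raise ValueError("focus counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(c0 > 0, 1.0 - c1 / np.where(c0 > 0, c0, 1.0), np.nan)
    return frac if frac.ndim else float(frac)


def classify_fast(fraction, threshold: float = FAST_RESOLVER_THRESHOLD):
    """Fast-resolver call: strictly more than ``threshold`` of foci resolved.

    NaN fractions (undefined, e.g. zero initial count) are classified False
    and should be excluded upstream.
    """
    frac = np.asarray(fraction, dtype=float)
    out = np.where(np.isnan(frac), False, frac > threshold)
    return out if out.ndim else bool(out)


def build_tracks(matches: pd.DataFrame, table_t0: pd.DataFrame,
                 table_t1: pd.DataFrame,
                 threshold: float = FAST_RESOLVER_THRESHOLD) -> pd.DataFrame:
    """Join matched nuclei with their per-timepoint focus counts.

    Returns one row per tracked cell: labels and counts at both timepoints,
    the resolution fraction (NaN when count_t0 == 0), a ``classifiable``
    flag, and the fast-resolver call.
    """
    c0 = table_t0.set_index("nucleus_label")["focus_count"]
    c1 = table_t1.set_index("nucleus_label")["focus_count"]
    rows = []
    for k, m in enumerate(matches.itertuples()):
        n0 = int(c0.loc[m.label_t0])
        n1 = int(c1.loc[m.label_t1])
        frac = resolution_fraction(n0, n1)
        rows.append((k, int(m.label_t0), int(m.label_t1), n0, n1, frac,
                     not np.isnan(frac),
                     bool(classify_fast(frac, threshold)) if not np.isnan(frac)
                     else False))
    return pd.DataFrame(rows, columns=[
        "cell_id", "nucleus_label_t0", "nucleus_label_t1", "count_t0",
        "count_t1", "resolution_fraction", "classifiable", "fast_resolver"])


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

@dataclass
class PopulationSummary:
    """Per-timepoint moments and smoothed normalized count histograms."""

    stats: pd.DataFrame                       # timepoint_min, n_cells, mean, sd, median
    histograms: dict[float, pd.DataFrame]     # timepoint -> (focus_count, probability)


def smoothed_histogram(counts: np.ndarray, bandwidth: float = 1.0,
                       n_bins: int | None = None) -> pd.DataFrame:
    """Normalized histogram over integer focus counts, smoothed with a
    Gaussian kernel (one bin per integer count) and renormalized to unit
    mass."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty sample")
    half = int(np.ceil(4 * bandwidth)) if bandwidth > 0 else 0
    # keep room above the largest count so smoothing is not clipped there
    top = (int(counts.max()) + half) if n_bins is None else n_bins - 1
    hist = np.bincount(counts, minlength=top + 1).astype(float)
    hist /= hist.sum()
    if bandwidth > 0:
        x = np.arange(-half, half + 1)
        kern = np.exp(-x ** 2 / (2 * bandwidth ** 2))
        kern /= kern.sum()
        hist = np.convolve(hist, kern, mode="same")
        hist /= hist.sum()
    return pd.DataFrame({"focus_count": np.arange(top + 1), "probability": hist})


def summarize(counts_by_timepoint: dict[float, np.ndarray],
              bandwidth: float = 1.0) -> PopulationSummary:
    """Population summary per timepoint: n, mean, sample SD (n-1), median,
    and a smoothed normalized histogram of foci per cell."""
    rows, hists = [], {}
    for t in sorted(counts_by_timepoint):
        c = np.asarray(counts_by_timepoint[t], dtype=float)
        if c.size == 0:
            raise ValueError(f"no cells at timepoint {t}")
        sd = float(c.std(ddof=1)) if c.size > 1 else 0.0
        rows.append((float(t), int(c.size), float(c.mean()), sd,
                     float(np.median(c))))
        hists[float(t)] = smoothed_histogram(c.astype(int), bandwidth)
    stats_df = pd.DataFrame(rows, columns=["timepoint_min", "n_cells",
                                           "mean", "sd", "median"])
    return PopulationSummary(stats=stats_df, histograms=hists)


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

def compare_ttest(counts_a, counts_b, welch: bool = False
                  ) -> tuple[float, float]:
    """Two-sample Student t-test (pooled variance, two-sided).

    Welch's unequal-variance variant is available behind ``welch=True``.
    Zero pooled variance with equal means returns (0.0, 1.0).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf * np.sign(a.mean() - b.mean())), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def intensity_count_correlation(table: pd.DataFrame) -> float:
    """Pearson correlation between mean nuclear intensity and focus count.

    Used to check that whole-nucleus brightness carries no information
    about focus number (the reason intensity-gated sorting cannot find
    fast resolvers). Zero variance in either variable is undefined: NaN
    with a warning.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 nuclei")
    x = table["mean_nuclear_intensity"].to_numpy(float)
    y = table["focus_count"].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def speed_ratio(ref_times, ref_medians, pop_times, pop_medians) -> float:
    """How many times faster the population resolves foci than the reference.

    For the population's median count at its earliest comparable timepoint
    t_pop, linear interpolation on the reference median-vs-time curve gives
    the time t_ref at which the reference reaches the same median; the
    ratio is t_ref / t_pop. Both curves must be non-increasing; a median
    outside the observed reference range at every timepoint is undefined
    (NaN with a warning) — extrapolation is refused.
    """
    rt = np.asarray(ref_times, dtype=float)
    rm = np.asarray(ref_medians, dtype=float)
    pt = np.asarray(pop_times, dtype=float)
    pm = np.asarray(pop_medians, dtype=float)
    for name, arr in (("reference", rm), ("population", pm)):
        if np.any(np.diff(arr) > 0):
            raise ValueError(f"{name} median curve must be non-increasing")
    lo, hi = rm.min(), rm.max()
    for t_pop, m in zip(pt, pm):
        if lo <= m <= hi:
            # invert the decreasing reference curve by linear interpolation
            t_ref = float(np.interp(m, rm[::-1], rt[::-1]))
            return t_ref / float(t_pop)
    warnings.warn("population medians never cross the reference range",
                  stacklevel=2)
    return float("nan")
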