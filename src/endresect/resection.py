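"""Per-hotspot resection estimators: minimum, mean E(x) and maximum.

All three operate on one *side profile* at a time: a 1-D array of binned
endpoint intensity indexed by distance from the hotspot center, built from
the strand that reports that side (top strand = right side, bottom strand =
left side).  Bin ``i`` (1-based) covers distances ``[(i-1)*bin, i*bin)`` and
is represented by its midpoint ``i*bin - bin/2``.

* mean resection: the expected value of the resection-endpoint distribution,
  ``E(x) = sum x_i p_i`` over 10-bp bins 21..400 (distances 200-4000 bp; the
  first 20 bins — the central peak and gap — never contribute), with
  ``p_i`` the bin's share of the summed intensity.
* minimum resection: slide a window of 10-bp bins from the long-range
  resection peak toward the center; the first window whose one-sample t test
  (alternative "less") against the mean of the +/-500 bp region around the
  peak reaches ``p <= alpha`` marks the gap edge.
* maximum resection: slide a window of 20-bp bins outward from the
  long-range peak until more than half its bins are at or below the dynamic
  background (the maximum 20-bp bin intensity 5-6 kb from the center); the
  last scanned bin above background is the maximum resection endpoint.

Undefined estimates (all-zero side, background above peak, no significant
window) propagate as NaN, never as zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ProfileMatrix, smooth_profile

logger = logging.getLogger(__name__)

SIDES = ("left", "right")


@dataclass
class ResectionEstimate:
    """Resection distances (bp) for one hotspot side; NaN = undefined."""

    hotspot: int
    side: str
    min_resection: float
    mean_resection: float
    max_resection: float
    background: float

    @property
    def flags(self) -> str:
        out = []
        for name in ("min", "mean", "max"):
            if np.isnan(getattr(self, f"{name}_resection")):
                out.append(f"{name}_undefined")
        return ";".join(out) or "ok"


def side_profile(matrix: ProfileMatrix, row: int, side: str) -> np.ndarray:
    """Distance-indexed side profile from the strand reporting that side."""
    n_bins = matrix.top.shape[1]
    half = n_bins // 2
    if side == "right":
        return matrix.top[row, half:]
    if side == "left":
        return matrix.bottom[row, :half][::-1]
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def _bin_midpoints(n: int, bin_size: int) -> np.ndarray:
    return (np.arange(1, n + 1) * bin_size) - bin_size / 2


def mean_resection(profile: np.ndarray, bin_size: int = 10,
                   first_bin: int = 21, last_bin: int = 400) -> float:
    """E(x) over bins ``first_bin..last_bin`` (1-based, inclusive).

    ``x_i`` is the bin midpoint distance, ``p_i`` the bin's intensity share;
    the result is scale-invariant by construction.
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) < last_bin:
        raise ValueError(f"side profile has {len(profile)} bins, "
                         f"needs {last_bin}")
    window = profile[first_bin - 1:last_bin]
    total = window.sum()
    if total <= 0:
        return float("nan")
    x = _bin_midpoints(len(profile), bin_size)[first_bin - 1:last_bin]
    return float((x * window).sum() / total)


def long_range_peak(profile: np.ndarray, bin_size: int,
                    min_distance: float = 300.0) -> int | None:
    """Index of the long-range resection peak: argmax of the smoothed side
    profile at distances beyond ``min_distance`` bp (leftmost tie)."""
    profile = np.asarray(profile, dtype=float)
    smooth = smooth_profile(profile, bin_size)
    start = int(np.ceil(min_distance / bin_size))
    if start >= len(profile) or smooth[start:].max() <= 0:
        return None
    return start + int(np.argmax(smooth[start:]))


def min_resection(profile: np.ndarray, bin_size: int = 10,
                  window_bins: int = 5, alpha: float = 0.05,
                  peak_min_distance: float = 300.0,
                  ref_halfwidth: float = 500.0) -> float:
    """Gap-edge (minimum resection) distance via the sliding-window t test.

    Returns the |offset| of the midpoint of the first window, sliding from
    the long-range peak toward the center, whose mean is significantly below
    the reference mean (bins within ``ref_halfwidth`` bp of the peak).
    NaN when no window reaches significance before the center.
    """
    profile = np.asarray(profile, dtype=float)
    peak = long_range_peak(profile, bin_size, peak_min_distance)
    if peak is None:
        return float("nan")
    ref_bins = int(round(ref_halfwidth / bin_size))
    ref = profile[max(0, peak - ref_bins):peak + ref_bins + 1]
    mu = float(ref.mean())
    half = window_bins // 2
    x = _bin_midpoints(len(profile), bin_size)
    # vectorized one-sided t test over every fully contained window midpoint
    last_mid = min(peak, len(profile) - window_bins + half)
    mids = np.arange(half, last_mid + 1)
    if len(mids) == 0:
        return float("nan")
    win = np.lib.stride_tricks.sliding_window_view(
        profile, window_bins)[mids - half]
    mean = win.mean(axis=1)
    sd = win.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - mu) / (sd / np.sqrt(window_bins))
        p = stats.t.cdf(t, df=window_bins - 1)
    degenerate = sd == 0
    p[degenerate] = np.where(mean[degenerate] < mu, 0.0, 1.0)
    hits = np.flatnonzero(p <= alpha)
    if len(hits) == 0:
        return float("nan")
    # first significant window encountered sliding inward = largest midpoint
    return float(x[mids[hits[-1]]])


def max_resection(profile: np.ndarray, bin_size: int = 20,
                  window_bins: int = 5,
                  background_range: tuple[float, float] = (5000.0, 6000.0),
                  peak_min_distance: float = 300.0) -> tuple[float, float]:
    """Maximum resection distance via the dynamic-background outward scan.

    Returns ``(max_resection, background)``; NaN when the background matches
    or exceeds the peak intensity or no bin beyond the peak clears it.
    """
    profile = np.asarray(profile, dtype=float)
    lo_bin = int(background_range[0] // bin_size)
    hi_bin = int(background_range[1] // bin_size)
    if len(profile) < hi_bin:
        raise ValueError(f"side profile must extend to "
                         f"{background_range[1]:.0f} bp")
    background = float(profile[lo_bin:hi_bin].max())
    peak = long_range_peak(profile, bin_size, peak_min_distance)
    if peak is None or profile[peak] <= background:
        return float("nan"), background
    x = _bin_midpoints(len(profile), bin_size)
    stop = len(profile)  # end of the scanned region (terminating window incl.)
    for start in range(peak, len(profile) - window_bins + 1):
        window = profile[start:start + window_bins]
        if (window <= background).sum() > window_bins / 2:
            stop = start + window_bins
            break
    above = np.flatnonzero(profile[peak:stop] > background)
    if len(above) == 0:
        return float("nan"), background
    return float(x[peak + above[-1]]), background


def estimate_resection(matrix10: ProfileMatrix, matrix20: ProfileMatrix,
                       window_bins: int = 5, alpha: float = 0.05) -> pd.DataFrame:
    """All three estimators for every hotspot and side.

    ``matrix10``: 10-bp bins over +/-4 kb (mean and minimum resection);
    ``matrix20``: 20-bp bins over at least +/-6 kb (maximum resection).
    """
    if not np.array_equal(matrix10.hotspot_ids, matrix20.hotspot_ids):
        raise ValueError("profile matrices must cover the same hotspots")
    rows = []
    for i, hid in enumerate(matrix10.hotspot_ids):
        for side in SIDES:
            p10 = side_profile(matrix10, i, side)
            p20 = side_profile(matrix20, i, side)
            mx, bg = max_resection(p20, matrix20.bin_size, window_bins)
            est = ResectionEstimate(
                hotspot=int(hid), side=side,
                min_resection=min_resection(p10, matrix10.bin_size,
                                            window_bins, alpha),
                mean_resection=mean_resection(p10, matrix10.bin_size),
                max_resection=mx, background=bg)
            rows.append({**vars(est), "flags": est.flags})
    return pd.DataFrame(rows)


def summarize_resection(per_hotspot: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide summary (mean/median/quartiles) per estimator, NaN-aware."""
    out = {}
    for col in ("min_resection", "mean_resection", "max_resection"):
        v = per_hotspot[col].dropna()
        out[col] = {
            "n_defined": len(v), "mean": v.mean(), "median": v.median(),
            "q25": v.quantile(0.25), "q75": v.quantile(0.75),
        }
    return pd.DataFrame(out).T


def compare_resection(group_a: pd.Series | np.ndarray,
                      group_b: pd.Series | np.ndarray,
                      mu_offset: float = 10.0) -> dict:
    """Genotype comparison: one-sample t test on paired per-hotspot
    differences against a null offset (the replicate-noise scale).

    H1: mean(b - a) > mu_offset.  Unequal hotspot sets are restricted to the
    shared index with a warning.  Returns the t statistic, p value, median
    difference (effect size) and the n used.
    """
    a, b = pd.Series(group_a), pd.Series(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if not a.index.equals(b.index):
        common = a.index.intersection(b.index)
        logger.warning("unequal hotspot sets; restricting to %d shared", len(common))
        a, b = a.loc[common], b.loc[common]
    diff = (b - a).dropna().to_numpy()
    if np.ptp(diff) == 0:  # degenerate: a constant shift decides the test
        t = type("T", (), {})()
        t.statistic = float("inf") if diff[0] > mu_offset else -float("inf")
        t.pvalue = 0.0 if diff[0] > mu_offset else 1.0
    else:
        t = stats.ttest_1samp(diff, popmean=mu_offset, alternative="greater")
    return {"t": float(t.statistic), "p": float(t.pvalue),
            "median_diff": float(np.median(diff)), "n": len(diff),
            "mu_offset": mu_offset}
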