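"""Independent brute-force oracles for the resection estimators.

Each oracle evaluates *every* candidate window literally with scipy's t test
(or plain arithmetic) instead of the vectorized scans used by the package;
the estimators must agree with them exactly.
"""

import numpy as np
from scipy import stats

from endresect.resection import long_range_peak


def oracle_mean(profile, bin_size=10, first_bin=21, last_bin=400):
    """Direct weighted mean of bin-midpoint distances."""
    profile = np.asarray(profile, dtype=float)
    w = profile[first_bin - 1:last_bin]
    if w.sum() <= 0:
        return float("nan")
    x = np.array([i * bin_size - bin_size / 2
                  for i in range(first_bin, last_bin + 1)])
    return float(np.average(x, weights=w))


def _p_less(window, mu):
    if np.ptp(window) == 0:
        return 0.0 if window[0] < mu else 1.0
    return float(stats.ttest_1samp(window, mu, alternative="less").pvalue)


def oracle_min(profile, bin_size=10, window_bins=5, alpha=0.05,
               peak_min_distance=300.0, ref_halfwidth=500.0):
    """Exhaustive window-by-window evaluation of the gap-edge scan."""
    profile = np.asarray(profile, dtype=float)
    peak = long_range_peak(profile, bin_size, peak_min_distance)
    if peak is None:
        return float("nan")
    ref_bins = int(round(ref_halfwidth / bin_size))
    mu = float(profile[max(0, peak - ref_bins):peak + ref_bins + 1].mean())
    half = window_bins // 2
    last_mid = min(peak, len(profile) - window_bins + half)
    for mid in range(last_mid, half - 1, -1):
        window = profile[mid - half:mid - half + window_bins]
        if _p_less(window, mu) <= alpha:
            return float((mid + 1) * bin_size - bin_size / 2)
    return float("nan")


def oracle_max(profile, bin_size=20, window_bins=5,
               background_range=(5000.0, 6000.0), peak_min_distance=300.0):
    """Exhaustive outward scan with literal stop-rule evaluation."""
    profile = np.asarray(profile, dtype=float)
    lo = int(background_range[0] // bin_size)
    hi = int(background_range[1] // bin_size)
    background = float(profile[lo:hi].max())
    peak = long_range_peak(profile, bin_size, peak_min_distance)
    if peak is None or profile[peak] <= background:
        return float("nan")
    stop = len(profile)
    for start in range(peak, len(profile) - window_bins + 1):
        n_low = sum(1 for v in profile[start:start + window_bins]
                    if v <= background)
        if n_low > window_bins / 2:
            stop = start + window_bins
            break
    last = float("nan")
    for i in range(peak, stop):
        if profile[i] > background:
            last = float((i + 1) * bin_size - bin_size / 2)
    return last


def random_side_profile(rng, n_bins, kind=None):
    """Random side profiles spanning the estimators' qualitative regimes."""
    kind = kind if kind is not None else rng.integers(4)
    x = np.arange(n_bins, dtype=float)
    if kind == 0:      # noisy unimodal bump
        mu = rng.uniform(0.3, 0.8) * n_bins
        sd = rng.uniform(0.05, 0.2) * n_bins
        prof = 100 * np.exp(-0.5 * ((x - mu) / sd) ** 2)
        prof += rng.poisson(rng.uniform(0, 2), size=n_bins)
    elif kind == 1:    # step with read-less gap
        edge = rng.integers(n_bins // 4, 3 * n_bins // 4)
        prof = np.where(x >= edge, rng.uniform(5, 20), 0.0)
        prof += rng.poisson(0.5, size=n_bins)
    elif kind == 2:    # sparse counts
        prof = rng.poisson(rng.uniform(0.1, 1.5), size=n_bins).astype(float)
    else:              # flat / degenerate
        prof = np.full(n_bins, float(rng.integers(0, 3)))
    return prof
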