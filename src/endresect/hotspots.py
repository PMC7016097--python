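"""DSB hotspot intervals: reading, blacklisting, calling and comparison.

A hotspot is an interval around a SPO11 cut center (typically a SPO11-oligo
summit).  The caller provided here is deliberately a simple, deterministic
fold-enrichment window scanner — a testable stand-in for the external peak
caller used on real libraries, not a re-implementation of it.  It scores
pooled-strand endpoint counts in sliding windows against the uniform
genome-wide expectation and merges enriched windows into peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .tracks import EndpointTrack, TrackError

logger = logging.getLogger(__name__)

HOTSPOT_COLUMNS = ["chrom", "start", "end", "center", "heat", "blacklisted"]


@dataclass(frozen=True)
class Hotspot:
    """One DSB hotspot: half-open interval with a cut center and a heat score."""

    chrom: str
    start: int
    end: int
    center: int
    heat: float = 0.0
    blacklisted: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"zero/negative-length interval {self.start}-{self.end}")
        if not (self.start <= self.center < self.end):
            raise ValueError(f"center {self.center} outside [{self.start}, {self.end})")


@dataclass
class HotspotSet:
    """Table of hotspots; ``active`` excludes blacklisted entries."""

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=HOTSPOT_COLUMNS))

    def __post_init__(self) -> None:
        df = self.data
        for col in HOTSPOT_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"hotspot table missing column {col!r}")
        if len(df):
            if (df["end"] <= df["start"]).any():
                raise ValueError("zero/negative-length hotspot interval")
            if ((df["center"] < df["start"]) | (df["center"] >= df["end"])).any():
                raise ValueError("hotspot center outside its interval")

    @classmethod
    def from_hotspots(cls, hs: list[Hotspot]) -> "HotspotSet":
        return cls(pd.DataFrame([vars(h) for h in hs], columns=HOTSPOT_COLUMNS))

    @property
    def active(self) -> pd.DataFrame:
        """Hotspots retained for downstream statistics (not blacklisted)."""
        return self.data[~self.data["blacklisted"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self):
        for row in self.data.itertuples(index=False):
            yield Hotspot(row.chrom, int(row.start), int(row.end),
                          int(row.center), float(row.heat), bool(row.blacklisted))

    def to_bed(self, path: str | Path) -> None:
        """BED output with the fold-enrichment/heat in the score column."""
        df = self.data
        bed = pd.DataFrame({
            "chrom": df["chrom"], "start": df["start"], "end": df["end"],
            "name": [f"hotspot_{i}" for i in range(len(df))],
            "score": df["heat"], "strand": ".",
        })
        bed.to_csv(path, sep="\t", header=False, index=False)

    def summit_table(self, path: str | Path) -> None:
        """Side table of summit offsets from interval starts (narrowPeak-style)."""
        df = self.data
        pd.DataFrame({
            "chrom": df["chrom"], "start": df["start"], "end": df["end"],
            "summit_offset": df["center"] - df["start"],
        }).to_csv(path, sep="\t", index=False)


def read_hotspots(path: str | Path, center_rule: str = "midpoint") -> HotspotSet:
    """Read hotspots from BED.

    ``center_rule="midpoint"`` places the center at the interval midpoint;
    ``"summit_column"`` reads a 7th column holding the summit offset from the
    interval start.  The 5th (score) column, when present, becomes the heat.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return HotspotSet()
    if df.shape[1] < 3:
        raise TrackError(f"{path}: BED needs at least 3 columns")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df["chrom"] = df["chrom"].astype(str)
    if (df["end"] <= df["start"]).any():
        line = int((df["end"] <= df["start"]).idxmax()) + 1
        raise TrackError(f"{path}: zero-length interval at line {line}")
    if center_rule == "midpoint":
        center = (df["start"] + df["end"]) // 2
    elif center_rule == "summit_column":
        if df.shape[1] < 7:
            raise TrackError(f"{path}: summit_column rule needs a 7th column")
        center = df["start"] + df[6].astype(int)
    else:
        raise ValueError(f"unknown center_rule {center_rule!r}")
    heat = df[4].astype(float) if df.shape[1] >= 5 else 0.0
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"].astype(int),
        "end": df["end"].astype(int), "center": center.astype(int),
        "heat": heat, "blacklisted": False,
    })
    return HotspotSet(out)


def _interval_trees(df: pd.DataFrame, slop: int = 0) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in df.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (max(0, s - slop), e + slop)
            for s, e in zip(grp["start"], grp["end"]))
    return trees


def apply_blacklist(hotspots: HotspotSet, blacklist: pd.DataFrame | HotspotSet) -> HotspotSet:
    """Flag hotspots sharing any base with a blacklist interval (half-open)."""
    bl = blacklist.data if isinstance(blacklist, HotspotSet) else blacklist
    if len(hotspots) == 0 or len(bl) == 0:
        return hotspots
    trees = _interval_trees(bl)
    df = hotspots.data.copy()
    flagged = [
        bool(trees.get(row.chrom) and trees[row.chrom].overlap(row.start, row.end))
        for row in df.itertuples(index=False)
    ]
    df["blacklisted"] = np.asarray(df["blacklisted"]) | np.asarray(flagged)
    n = int(np.sum(flagged))
    if n:
        logger.info("blacklisted %d of %d hotspots", n, len(df))
    return HotspotSet(df)


# ---------------------------------------------------------------------------
# fold-enrichment calling
# ---------------------------------------------------------------------------

def call_hotspots(track: EndpointTrack, window: int = 2000, min_fold: float = 2.5,
                  blacklist: pd.DataFrame | None = None,
                  summit_smooth: int = 50) -> HotspotSet:
    """Call enriched intervals by pooled-strand fold enrichment.

    Windows of ``window`` bp (stepped by half a window) whose pooled endpoint
    count exceeds ``min_fold`` times the uniform expectation
    (library_size * window / genome length) are merged into peaks.  The
    summit is the leftmost argmax of the ``summit_smooth``-bp moving-average
    per-base signal; the heat score is the peak's fold enrichment.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(track) == 0:
        logger.warning("empty track: returning empty hotspot set")
        return HotspotSet()
    genome_len = sum(track.genome.values())
    expected = track.library_size * window / genome_len
    step = max(1, window // 2)
    peaks: list[Hotspot] = []
    for chrom, length in track.genome.items():
        pos = track.positions(chrom)
        if len(pos) == 0:
            continue
        starts = np.arange(0, max(1, length - window + 1), step)
        counts = (np.searchsorted(pos, starts + window, side="left")
                  - np.searchsorted(pos, starts, side="left"))
        hot = counts > min_fold * expected
        if not hot.any():
            continue
        # merge overlapping/adjacent enriched windows into intervals
        idx = np.flatnonzero(hot)
        breaks = np.flatnonzero(np.diff(idx) * step > window)
        groups = np.split(idx, breaks + 1)
        for g in groups:
            s = int(starts[g[0]])
            e = int(min(length, starts[g[-1]] + window))
            n = int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
            if n == 0:
                continue
            # score: enrichment of the best window, not the merged interval
            fold = float(counts[g].max() / expected)
            local = pos[(pos >= s) & (pos < e)]
            base = np.bincount(local - s, minlength=e - s).astype(float)
            smooth = uniform_filter1d(base, size=max(1, summit_smooth))
            summit = s + int(np.argmax(smooth))  # argmax: leftmost tie
            peaks.append(Hotspot(chrom, s, e, summit, heat=fold))
    hs = HotspotSet.from_hotspots(peaks)
    if blacklist is not None and len(hs):
        hs = apply_blacklist(hs, blacklist)
        hs = HotspotSet(hs.active)
    logger.info("called %d peaks at fold > %.2f (window %d bp)",
                len(hs), min_fold, window)
    return hs


def split_subpeaks(profile: np.ndarray, min_prominence: float = 0.2) -> np.ndarray:
    """Split a per-base peak profile into subpeak summits.

    Local maxima with prominence >= ``min_prominence`` times the global
    maximum are returned left to right.  A flat profile yields a single
    summit at the midpoint.
    """
    profile = np.asarray(profile, dtype=float)
    if (profile < 0).any():
        raise ValueError("profile must be nonnegative")
    if len(profile) == 0:
        return np.array([], dtype=int)
    if np.ptp(profile) == 0:
        return np.array([len(profile) // 2])
    summits, _ = find_peaks(profile, prominence=min_prominence * profile.max())
    return summits


def summit_spacing(summits: np.ndarray) -> np.ndarray:
    """Distances between successive subpeak summits within one break."""
    summits = np.sort(np.asarray(summits))
    return np.diff(summits)


def overlap_sets(a: HotspotSet, b: HotspotSet, slop: int = 0):
    """Compare two hotspot sets by any-overlap matching after ``slop`` expansion.

    Returns ``(shared, a_only, b_only, jaccard)`` where ``shared`` counts
    intervals of ``a`` overlapping any interval of ``b`` after both are
    expanded by ``slop`` bp, and the Jaccard index is
    shared / (shared + a_only + b_only).
    """
    if slop < 0:
        raise ValueError("slop must be nonnegative")
    if len(a) == 0 or len(b) == 0:
        return 0, len(a), len(b), 0.0
    # expansion on one side only, so two intervals match iff their gap <= slop
    trees_b = _interval_trees(b.data, slop=slop)
    trees_a = _interval_trees(a.data, slop=slop)
    a_hit = sum(
        bool(trees_b.get(r.chrom) and trees_b[r.chrom].overlap(r.start, r.end))
        for r in a.data.itertuples(index=False))
    b_hit = sum(
        bool(trees_a.get(r.chrom) and trees_a[r.chrom].overlap(r.start, r.end))
        for r in b.data.itertuples(index=False))
    shared = min(a_hit, b_hit)
    a_only = len(a) - a_hit
    b_only = len(b) - b_hit
    denom = shared + a_only + b_only
    return shared, a_only, b_only, (shared / denom if denom else 0.0)
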