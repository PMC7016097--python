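"""Binned, strand-separated endpoint profiles around hotspot centers.

A ProfileMatrix holds one row per hotspot and one column per offset bin over
a symmetric window around the center, separately for top (+) and bottom (-)
strand endpoints.  Aggregation averages rows; height matching rescales one
aggregate so its distal-resection flank maximum equals a reference's,
leaving the central region comparable by subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .hotspots import HotspotSet
from .tracks import EndpointTrack

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Per-hotspot binned endpoint intensity, one matrix per strand."""

    hotspot_ids: np.ndarray      # (n,)
    top: np.ndarray              # (n, 2W/bin) intensity, raw counts or RPM
    bottom: np.ndarray
    halfwidth: int               # W, bp
    bin_size: int                # bp
    normalized: bool = False     # True once RPM-scaled

    def __post_init__(self) -> None:
        n_bins = 2 * self.halfwidth // self.bin_size
        for m in (self.top, self.bottom):
            if m.shape != (len(self.hotspot_ids), n_bins):
                raise ValueError(f"matrix shape {m.shape} != "
                                 f"({len(self.hotspot_ids)}, {n_bins})")
            if (m < 0).any():
                raise ValueError("intensities must be nonnegative")

    @property
    def offsets(self) -> np.ndarray:
        """Bin midpoints in bp relative to the hotspot center."""
        edges = np.arange(-self.halfwidth, self.halfwidth, self.bin_size)
        return edges + self.bin_size / 2

    @property
    def pooled(self) -> np.ndarray:
        return self.top + self.bottom

    def to_tsv(self, prefix: str) -> None:
        """Persist as one hotspots x bins TSV per strand."""
        for name, m in (("top", self.top), ("bottom", self.bottom)):
            pd.DataFrame(m, index=self.hotspot_ids,
                         columns=self.offsets).to_csv(
                f"{prefix}.{name}.tsv", sep="\t")


@dataclass
class AggregateProfile:
    """Across-hotspot mean intensity per offset bin and strand."""

    offsets: np.ndarray
    top: np.ndarray
    bottom: np.ndarray
    bin_size: int
    smoothing: str = "none"

    @property
    def pooled(self) -> np.ndarray:
        return self.top + self.bottom

    def to_tsv(self, path: str) -> None:
        pd.DataFrame({"offset": self.offsets, "top": self.top,
                      "bottom": self.bottom}).to_csv(path, sep="\t", index=False)


def bin_endpoints(track: EndpointTrack, hotspots: HotspotSet, halfwidth: int,
                  bin_size: int, rpm: bool = False) -> ProfileMatrix:
    """Bin endpoints into per-hotspot strand-separated offset histograms.

    An endpoint at offset ``o`` from the center lands in bin
    ``floor((o + W)/bin)``; windows exceeding chromosome bounds are truncated
    (with a warning) by construction of the histogram.
    """
    if halfwidth % bin_size:
        raise ValueError("halfwidth must be a multiple of bin_size")
    active = hotspots.active
    n_bins = 2 * halfwidth // bin_size
    top = np.zeros((len(active), n_bins))
    bottom = np.zeros((len(active), n_bins))
    edges = np.arange(-halfwidth, halfwidth + bin_size, bin_size)

    by_chrom = {c: {s: track.positions(c, s) for s in "+-"}
                for c in active["chrom"].unique()}
    truncated = 0
    for i, row in enumerate(active.itertuples(index=False)):
        length = track.genome.get(row.chrom)
        if length is not None and (row.center - halfwidth < 0
                                   or row.center + halfwidth > length):
            truncated += 1
        for strand, mat in (("+", top), ("-", bottom)):
            pos = by_chrom[row.chrom][strand]
            lo = np.searchsorted(pos, row.center - halfwidth, side="left")
            hi = np.searchsorted(pos, row.center + halfwidth, side="left")
            offs = pos[lo:hi] - row.center
            mat[i], _ = np.histogram(offs, bins=edges)
    if truncated:
        logger.warning("%d hotspot window(s) truncated at chromosome bounds",
                       truncated)
    if rpm:
        lib = track.library_size
        if lib == 0:
            raise ValueError("RPM scaling requested on an empty track")
        top *= 1e6 / lib
        bottom *= 1e6 / lib
    return ProfileMatrix(np.arange(len(active)), top, bottom,
                         halfwidth, bin_size, normalized=rpm)


def smooth_profile(values: np.ndarray, bin_size: int, span_bp: float = 50.0) -> np.ndarray:
    """Low-pass smoothing that keeps the argmax of a delta at its offset."""
    sigma = max(span_bp / bin_size / 2.0, 0.5)
    return gaussian_filter1d(np.asarray(values, float), sigma=sigma, mode="nearest")


def aggregate(matrix: ProfileMatrix, smooth: bool = False,
              smooth_span: float = 50.0) -> AggregateProfile:
    """Column means across hotspots (pooled = top + bottom before smoothing)."""
    if len(matrix.hotspot_ids) == 0:
        raise ValueError("cannot aggregate an empty profile matrix")
    top = matrix.top.mean(axis=0)
    bottom = matrix.bottom.mean(axis=0)
    smoothing = "none"
    if smooth:
        top = smooth_profile(top, matrix.bin_size, smooth_span)
        bottom = smooth_profile(bottom, matrix.bin_size, smooth_span)
        smoothing = f"gaussian:{smooth_span}bp"
    return AggregateProfile(matrix.offsets, top, bottom, matrix.bin_size, smoothing)


def flank_mask(offsets: np.ndarray, flank_range: tuple[float, float]) -> np.ndarray:
    lo, hi = flank_range
    return (np.abs(offsets) >= lo) & (np.abs(offsets) <= hi)


def match_heights(sample: AggregateProfile, reference: AggregateProfile,
                  flank_range: tuple[float, float] = (800, 3000),
                  use: str = "max") -> AggregateProfile:
    """Rescale ``sample`` so its flank signal matches ``reference``.

    The scale factor is computed over the distal resection flanks only
    (default |offset| in [800, 3000] bp), from pooled-strand maxima
    (``use="max"``) or areas (``use="area"``), so central-region differences
    between enzyme conditions are preserved for subtraction.
    """
    if not np.array_equal(sample.offsets, reference.offsets):
        raise ValueError("profiles must share offsets")
    mask = flank_mask(sample.offsets, flank_range)
    stat = {"max": np.max, "area": np.sum}[use]
    ref_stat = stat(reference.pooled[mask])
    samp_stat = stat(sample.pooled[mask])
    if ref_stat <= 0:
        raise ValueError("reference has no positive flank signal")
    if samp_stat <= 0:
        raise ValueError("sample has no positive flank signal")
    scale = ref_stat / samp_stat
    return replace(sample, top=sample.top * scale, bottom=sample.bottom * scale)
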