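"""Strand-annotated END-seq endpoint tracks and their on-disk formats.

The unit observation of an END-seq library is the genomic position of an
adapter-ligated read 5' end: for a resected DSB end this is the ssDNA-dsDNA
junction, for a protein-blocked end it is the cut site itself.  A track is a
weighted multiset of such endpoints, one per strand, together with the genome
it lives on.  All coordinates are 0-based, half-open (BED-native); conversion
to other conventions happens only at file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: canonical column order of the endpoint table
ENDPOINT_COLUMNS = ["chrom", "pos", "strand", "weight"]


class TrackError(ValueError):
    """Raised for malformed endpoint files or coordinate violations."""


@dataclass
class EndpointTrack:
    """Weighted, strand-annotated genomic endpoint positions.

    Parameters
    ----------
    data
        DataFrame with at least the columns ``chrom`` (str), ``pos``
        (0-based int), ``strand`` (``+``/``-``) and ``weight`` (count > 0).
        Extra columns (e.g. a ``species`` flag emitted by the simulator) are
        carried along untouched by subsetting operations.
    genome
        Mapping chrom name -> chromosome length in bp.  Every record must
        satisfy ``0 <= pos < genome[chrom]``.
    """

    data: pd.DataFrame
    genome: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ENDPOINT_COLUMNS if c not in self.data.columns]
        if missing:
            raise TrackError(f"endpoint table missing columns: {missing}")
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        bad_strand = ~df["strand"].isin(STRANDS)
        if bad_strand.any():
            raise TrackError(
                f"invalid strand value(s): {sorted(df.loc[bad_strand, 'strand'].unique())}"
            )
        unknown = set(df["chrom"].unique()) - set(self.genome)
        if unknown:
            raise TrackError(f"chromosome(s) not in genome: {sorted(unknown)}")
        lengths = df["chrom"].map(self.genome).to_numpy()
        pos = df["pos"].to_numpy()
        out = (pos < 0) | (pos >= lengths)
        if out.any():
            i = int(np.flatnonzero(out)[0])
            raise TrackError(
                f"position {pos[i]} outside [0, {lengths[i]}) on "
                f"{df['chrom'].iloc[i]} (half-open convention)"
            )
        if (df["weight"].to_numpy() <= 0).any():
            raise TrackError("endpoint weights must be positive")

    # -- basic properties ---------------------------------------------------

    @property
    def library_size(self) -> float:
        """Total weighted endpoint count (the RPM denominator)."""
        return float(self.data["weight"].sum())

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, strand: str | None = None, species=None) -> "EndpointTrack":
        """Restrict to one strand and/or a set of species flags."""
        df = self.data
        if strand is not None:
            if strand not in STRANDS:
                raise TrackError(f"strand must be one of {STRANDS}, got {strand!r}")
            df = df[df["strand"] == strand]
        if species is not None:
            if "species" not in df.columns:
                raise TrackError("track carries no species flags")
            wanted = {species} if isinstance(species, str) else set(species)
            df = df[df["species"].isin(wanted)]
        return EndpointTrack(df.reset_index(drop=True), dict(self.genome))

    def positions(self, chrom: str, strand: str | None = None) -> np.ndarray:
        """Sorted endpoint positions on one chromosome (weights expanded).

        Weights are expanded by repetition so that downstream counting code
        can treat the result as one entry per sequenced endpoint.
        """
        df = self.data
        mask = df["chrom"] == chrom
        if strand is not None:
            mask &= df["strand"] == strand
        sub = df.loc[mask, ["pos", "weight"]]
        pos = np.repeat(sub["pos"].to_numpy(), sub["weight"].to_numpy().astype(int))
        return np.sort(pos)


def concat_tracks(tracks: list[EndpointTrack]) -> EndpointTrack:
    """Merge endpoint tracks (e.g. replicate libraries) into one."""
    if not tracks:
        raise TrackError("no tracks to merge")
    genome: dict[str, int] = {}
    for t in tracks:
        for c, n in t.genome.items():
            if genome.get(c, n) != n:
                raise TrackError(f"conflicting lengths for {c}")
            genome[c] = n
    data = pd.concat([t.data for t in tracks], ignore_index=True)
    return EndpointTrack(data, genome)


# ---------------------------------------------------------------------------
# genome / BED6 / bedGraph I/O
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom-sizes file into a name -> length mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": int})
    return dict(zip(df["chrom"], df["length"]))


def write_genome(genome: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(genome.items(), columns=["chrom", "length"]).to_csv(
        path, sep="\t", header=False, index=False)


def read_endpoints(path: str | Path, genome: dict[str, int] | str | Path) -> EndpointTrack:
    """Read adapter-ligated endpoints from a BED6 file.

    One record per line; the BED score column is ignored and every record
    gets weight 1 (duplicates are kept, mirroring peak calling with
    ``--keep-dup=all``).  The BED name column, if informative, is kept as the
    ``species`` flag used by the enzyme-condition simulator.
    """
    if not isinstance(genome, dict):
        genome = read_genome(genome)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise TrackError(f"malformed BED6 file {path}: {exc}") from exc
    if df[["start", "end", "strand"]].isna().any().any():
        line = int(df[["start", "end", "strand"]].isna().any(axis=1).idxmax()) + 1
        raise TrackError(f"malformed BED6 record at line {line} of {path}")
    bad = ~df["strand"].isin(STRANDS)
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise TrackError(f"invalid strand at line {line} of {path} "
                         f"(expected + or -)")
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["start"].astype(int),
        "strand": df["strand"],
        "weight": 1,
    })
    if df["name"].notna().any() and (df["name"].fillna(".") != ".").any():
        out["species"] = df["name"].fillna(".")
    track = EndpointTrack(out, genome)
    logger.info("read %d endpoints from %s (duplicates kept)", len(track), path)
    return track


def write_endpoints(track: EndpointTrack, path: str | Path) -> None:
    """Write a track as BED6 (name column = species flag when present)."""
    df = track.data
    name = df["species"] if "species" in df.columns else "."
    bed = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["pos"],
        "end": df["pos"] + 1,
        "name": name,
        "score": df["weight"],
        "strand": df["strand"],
    })
    bed.sort_values(["chrom", "start", "strand"], kind="stable").to_csv(
        path, sep="\t", header=False, index=False)


def per_base_counts(track: EndpointTrack, strand: str = "both") -> pd.DataFrame:
    """Weighted endpoint count per base, as chrom/pos/count rows."""
    df = track.data
    if strand != "both":
        if strand not in STRANDS:
            raise TrackError(f"strand must be +, - or both, got {strand!r}")
        df = df[df["strand"] == strand]
    counts = (df.groupby(["chrom", "pos"], sort=True, observed=True)["weight"]
                .sum().reset_index(name="count"))
    return counts


def write_bedgraph(track: EndpointTrack, path: str | Path,
                   strand: str = "both", normalize: str = "raw") -> None:
    """Write per-base endpoint coverage as bedGraph.

    ``normalize="RPM"`` scales counts by 1e6 / library size of the *whole*
    track, matching genome-browser normalization to sequencing depth.  Runs
    of identical values are merged into single intervals.
    """
    if normalize not in ("raw", "RPM"):
        raise TrackError(f"normalize must be 'raw' or 'RPM', got {normalize!r}")
    counts = per_base_counts(track, strand=strand)
    if normalize == "RPM":
        lib = track.library_size
        if lib == 0:
            raise TrackError("RPM normalization requested on an empty track")
        values = counts["count"].to_numpy(float) * 1e6 / lib
    else:
        values = counts["count"].to_numpy(float)
    with open(path, "w") as fh:
        for chrom, grp in counts.assign(value=values).groupby("chrom", sort=True,
                                                              observed=True):
            pos = grp["pos"].to_numpy()
            val = grp["value"].to_numpy()
            # merge adjacent single-base intervals with equal value
            start = 0
            for i in range(1, len(pos) + 1):
                if (i == len(pos) or pos[i] != pos[i - 1] + 1
                        or val[i] != val[i - 1]):
                    fh.write(f"{chrom}\t{pos[start]}\t{pos[i - 1] + 1}\t"
                             f"{val[start]:.10g}\n")
                    start = i


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph file into chrom/start/end/value rows."""
    try:
        return pd.read_csv(path, sep="\t", header=None,
                           names=["chrom", "start", "end", "value"],
                           dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])


def bedgraph_per_base(bg: pd.DataFrame) -> pd.DataFrame:
    """Expand bedGraph intervals back to per-base chrom/pos/count rows."""
    if len(bg) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "count"])
    reps = (bg["end"] - bg["start"]).to_numpy()
    chrom = np.repeat(bg["chrom"].to_numpy(), reps)
    pos = np.concatenate([np.arange(s, e) for s, e in zip(bg["start"], bg["end"])])
    val = np.repeat(bg["value"].to_numpy(), reps)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "count": val})
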