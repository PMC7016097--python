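import numpy as np
import pandas as pd
import pytest

from endresect import EndpointTrack, HotspotSet


def make_track(positions, strands=None, chrom="chr1", length=1_000_000,
               weights=None, species=None) -> EndpointTrack:
    """Small literal endpoint track for unit tests."""
    positions = np.asarray(positions, dtype=int)
    n = len(positions)
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": positions,
        "strand": strands if strands is not None else ["+"] * n,
        "weight": weights if weights is not None else 1,
    })
    if species is not None:
        df["species"] = species
    return EndpointTrack(df, {chrom: length})


def make_hotspots(centers, halfwidth=1000, chrom="chr1") -> HotspotSet:
    centers = np.asarray(centers, dtype=int)
    return HotspotSet(pd.DataFrame({
        "chrom": chrom,
        "start": centers - halfwidth,
        "end": centers + halfwidth,
        "center": centers,
        "heat": 1.0,
        "blacklisted": False,
    }))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
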