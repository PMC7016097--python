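"""Generative model of an END-seq meiotic DSB library with known ground truth.

Each DSB hotspot receives a number of break events; every event falls into
one of four processing categories and emits exactly one top-strand and one
bottom-strand adapter-ligated endpoint:

* ``resected`` — both ends protein-free and fully resected: top-strand
  endpoint at ``cut + R_right``, bottom-strand at ``cut - R_left`` ("correct"
  polarity, reads flanking a read-less gap).
* ``spo11_ri`` — SPO11-bound recombination intermediate: the motif-proximal
  end retains SPO11 and is sequenced from the cut itself (a cut left of the
  hotspot center yields a *top*-strand central read; a cut right of center a
  *bottom*-strand central read — the "wrong" polarity), while the motif-distal
  end is fully resected.
* ``spo11_cc`` — unresected SPO11 cleavage complex: blunt two-ended break at
  the cut (top at ``cut+1``, bottom at ``cut-1``), both ends protein-bound.
* ``double_cut`` — two adjacent SPO11 cuts ``c1 < c2`` releasing the
  intervening fragment: bottom-strand endpoint at ``c1``, top-strand at
  ``c2``, both protein-bound, giving the "correct"-polarity strand gap equal
  to the inter-cut spacing.

Resection endpoint distances are the sum of a minimum-resection gap edge
(normal) and a long-range extension (gamma by default: positive and
right-skewed, matching the 1-3 kb endpoint spread of real libraries).
Spike-in cells each carry one fixed blunt break at a dedicated locus, and a
uniform background endpoint rate models unligated noise.  Every emitted
endpoint is reproducible from the returned truth table, and a fixed seed
gives byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tracks import EndpointTrack
from .hotspots import HotspotSet

logger = logging.getLogger(__name__)

CATEGORIES = ("resected", "spo11_ri", "spo11_cc", "double_cut")

#: endpoint species flags; protein-free species survive every blunting enzyme
SPECIES_FREE = frozenset({"free", "spike", "background"})
#: species removed unless ExoVII (or TDP2 for cc-like ends) is present
SPECIES_BOUND = frozenset({"spo11_ri", "spo11_cc", "double_cut"})

ENZYME_CONDITIONS = ("ExoVII_ExoT", "ExoT_only", "TDP2_ExoT", "MRN_CtIP_pre")


@dataclass
class TruthParameters:
    """Ground-truth parameters of a simulated END-seq library.

    The defaults are the calibrated wild-type conditions (see :func:`preset`);
    distances are bp, probabilities are per break event.
    """

    n_hotspots: int = 2000
    genome: dict[str, int] = field(default_factory=lambda: {"chr1": 60_000_000,
                                                            "chrS": 200_000})
    hotspot_chrom: str = "chr1"
    heat_rate: float | None = None   # exponential rate for hotspot heat; None = uniform
    # per-event processing category probabilities (remainder: no break emitted)
    p_resected: float = 0.89
    p_ri: float = 0.10
    p_cc: float = 0.01
    p_doublecut: float = 0.0
    # SPO11 cut placement
    displacement: float = 30.0       # |cut - center|, sign random per event
    # resection endpoint distance = gap edge + long-range extension
    gap_mean: float = 500.0
    gap_sd: float = 50.0
    long_family: str = "gamma"
    long_mean: float = 629.0
    long_sd: float = 153.0
    # double-cut spacing (uniform, inclusive ints)
    doublecut_low: int = 40
    doublecut_high: int = 60
    # library composition
    n_cells: int = 30000             # bulk cell-equivalents
    breaks_per_cell: float = 200.0   # hotspot break events per bulk cell
    spike_fraction: float = 0.02     # spike cells / bulk cells (1:50)
    spike_chrom: str = "chrS"
    spike_pos: int = 100_000
    background_rate: float = 1e-7    # endpoints per bp per strand
    reads_per_break: int = 1         # weight attached to each emitted endpoint
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_resected, self.p_ri, self.p_cc, self.p_doublecut)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("category probabilities must be in [0, 1]")
        if sum(probs) > 1 + 1e-12:
            raise ValueError(f"category probabilities sum to {sum(probs):.4f} > 1")
        if self.gap_mean <= 0 or self.long_mean <= 0 or self.long_sd <= 0:
            raise ValueError("distance parameters must be positive")
        if self.doublecut_low > self.doublecut_high:
            raise ValueError("double-cut spacing needs low <= high")
        if not (0 <= self.spike_fraction <= 1):
            raise ValueError("spike_fraction must be in [0, 1]")
        if self.long_family not in ("gamma", "lognormal"):
            raise ValueError(f"unknown long-range family {self.long_family!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def category_probs(self) -> np.ndarray:
        p = np.array([self.p_resected, self.p_ri, self.p_cc, self.p_doublecut])
        return np.append(p, max(0.0, 1.0 - p.sum()))  # last slot: no break

    @property
    def total_bulk_breaks(self) -> float:
        return self.n_cells * self.breaks_per_cell

    def long_draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Long-range extension distances from the configured family."""
        m, s = self.long_mean, self.long_sd
        if self.long_family == "gamma":
            shape = (m / s) ** 2
            return rng.gamma(shape, scale=s * s / m, size=n)
        sigma2 = np.log1p((s / m) ** 2)
        return rng.lognormal(np.log(m) - sigma2 / 2, np.sqrt(sigma2), size=n)

    def resection_distance(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Per-end distance from the cut to the sequenced ssDNA-dsDNA junction."""
        gap = np.clip(rng.normal(self.gap_mean, self.gap_sd, size=n), 50.0, None)
        return gap + self.long_draw(rng, n)

    def to_yaml(self, path: str | Path) -> None:
        """Persist the resolved parameters for provenance."""
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def hotspot_centers(params: TruthParameters) -> np.ndarray:
    """Evenly spaced hotspot centers on the bulk chromosome."""
    length = params.genome[params.hotspot_chrom]
    margin = 20_000
    centers = np.linspace(margin, length - margin, params.n_hotspots)
    return np.round(centers).astype(int)


def truth_hotspots(params: TruthParameters, halfwidth: int = 1000) -> HotspotSet:
    """The simulated hotspots as a HotspotSet (centers are ground truth)."""
    centers = hotspot_centers(params)
    df = pd.DataFrame({
        "chrom": params.hotspot_chrom,
        "start": centers - halfwidth,
        "end": centers + halfwidth,
        "center": centers,
        "heat": 1.0,
        "blacklisted": False,
    })
    return HotspotSet(df)


def simulate_library(params: TruthParameters,
                     rng: np.random.Generator | None = None
                     ) -> tuple[EndpointTrack, pd.DataFrame]:
    """Emit an endpoint track and its per-event truth table.

    Returns ``(track, truth)``; the truth table has one row per break event
    with columns ``hotspot``, ``category``, ``cut``, ``cut2``, ``top_pos``,
    ``bottom_pos``, ``top_species``, ``bottom_species`` (spike events carry
    hotspot id -1).  The track's ``species`` column drives
    :func:`apply_enzyme_condition`.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    centers = hotspot_centers(params)

    # per-hotspot event counts: Poisson around the heat-weighted mean
    if params.heat_rate is None:
        heat = np.ones(params.n_hotspots)
    else:
        heat = rng.exponential(1.0, size=params.n_hotspots)  # unit mean
    mean_events = params.total_bulk_breaks * heat / heat.sum()
    n_events = rng.poisson(mean_events)
    hot_idx = np.repeat(np.arange(params.n_hotspots), n_events)
    n = len(hot_idx)

    cat_idx = rng.choice(5, size=n, p=params.category_probs)
    keep = cat_idx < 4                       # drop "no break" slots
    hot_idx, cat_idx = hot_idx[keep], cat_idx[keep]
    n = len(hot_idx)
    center = centers[hot_idx]

    sign = rng.choice([-1, 1], size=n)
    cut = center + (sign * params.displacement).astype(int)
    dist_left = np.round(params.resection_distance(rng, n)).astype(int)
    dist_right = np.round(params.resection_distance(rng, n)).astype(int)
    spacing = rng.integers(params.doublecut_low, params.doublecut_high + 1, size=n)

    top_pos = np.empty(n, dtype=int)
    bottom_pos = np.empty(n, dtype=int)
    top_species = np.empty(n, dtype=object)
    bottom_species = np.empty(n, dtype=object)
    cut2 = np.full(n, -1, dtype=int)

    res = cat_idx == 0
    top_pos[res] = cut[res] + dist_right[res]
    bottom_pos[res] = cut[res] - dist_left[res]
    top_species[res] = bottom_species[res] = "free"

    ri = cat_idx == 1
    ri_left = ri & (cut <= center)           # cut left of center: top central read
    ri_right = ri & (cut > center)
    top_pos[ri_left] = cut[ri_left]
    top_species[ri_left] = "spo11_ri"
    bottom_pos[ri_left] = cut[ri_left] - dist_left[ri_left]
    bottom_species[ri_left] = "free"
    bottom_pos[ri_right] = cut[ri_right]
    bottom_species[ri_right] = "spo11_ri"
    top_pos[ri_right] = cut[ri_right] + dist_right[ri_right]
    top_species[ri_right] = "free"

    cc = cat_idx == 2
    top_pos[cc] = cut[cc] + 1
    bottom_pos[cc] = cut[cc] - 1
    top_species[cc] = bottom_species[cc] = "spo11_cc"

    dc = cat_idx == 3
    c1 = cut[dc] - spacing[dc] // 2
    c2 = c1 + spacing[dc]
    cut[dc] = c1
    cut2[dc] = c2
    bottom_pos[dc] = c1
    top_pos[dc] = c2
    top_species[dc] = bottom_species[dc] = "double_cut"

    # spike-in cells: one fixed blunt two-ended break each (exact count —
    # the mixing ratio of control cells is known, not sampled)
    n_spike = int(round(params.spike_fraction * params.n_cells))
    truth = pd.DataFrame({
        "hotspot": np.concatenate([hot_idx, np.full(n_spike, -1)]),
        "category": np.concatenate([np.array(CATEGORIES, dtype=object)[cat_idx],
                                    np.full(n_spike, "spike", dtype=object)]),
        "cut": np.concatenate([cut, np.full(n_spike, params.spike_pos)]),
        "cut2": np.concatenate([cut2, np.full(n_spike, -1)]),
        "top_pos": np.concatenate([top_pos, np.full(n_spike, params.spike_pos + 1)]),
        "bottom_pos": np.concatenate([bottom_pos, np.full(n_spike, params.spike_pos - 1)]),
        "top_species": np.concatenate([top_species,
                                       np.full(n_spike, "spike", dtype=object)]),
        "bottom_species": np.concatenate([bottom_species,
                                          np.full(n_spike, "spike", dtype=object)]),
    })
    truth["chrom"] = np.where(truth["hotspot"] >= 0,
                              params.hotspot_chrom, params.spike_chrom)

    # categorical text columns keep deep libraries memory-lean
    records = pd.DataFrame({
        "chrom": pd.Categorical(np.concatenate([truth["chrom"], truth["chrom"]])),
        "pos": np.concatenate([truth["top_pos"], truth["bottom_pos"]]),
        "strand": pd.Categorical(np.repeat(["+", "-"], len(truth))),
        "weight": params.reads_per_break,
        "species": pd.Categorical(np.concatenate([truth["top_species"],
                                                  truth["bottom_species"]])),
        "hotspot": np.concatenate([truth["hotspot"], truth["hotspot"]]),
    })

    # uniform background endpoints on both strands
    bg_parts = []
    for chrom, length in params.genome.items():
        for strand in "+-":
            k = rng.poisson(params.background_rate * length)
            if k:
                bg_parts.append(pd.DataFrame({
                    "chrom": chrom,
                    "pos": rng.integers(0, length, size=k),
                    "strand": strand,
                    "weight": params.reads_per_break,
                    "species": "background",
                    "hotspot": -1,
                }))
    if bg_parts:
        records = pd.concat([records] + bg_parts, ignore_index=True)
        for col in ("chrom", "strand", "species"):
            records[col] = records[col].astype("category")

    # clip pathological draws at chromosome bounds (documented degenerate case)
    lengths = records["chrom"].map(params.genome).to_numpy()
    records["pos"] = np.clip(records["pos"].to_numpy(), 0, lengths - 1)

    track = EndpointTrack(records.reset_index(drop=True), dict(params.genome))
    logger.info("simulated %d events (%d spike) -> %d endpoints, seed=%s",
                len(truth), n_spike, len(track), params.seed)
    return track, truth


def apply_enzyme_condition(track: EndpointTrack, condition: str,
                           efficiency: dict[str, float] | None = None,
                           mrn_efficiency: float = 0.9,
                           rng: np.random.Generator | None = None) -> EndpointTrack:
    """Model which DSB-end species each in-vitro blunting condition ligates.

    * ``ExoVII_ExoT`` — the full assay: protein-free ends plus SPO11-bound
      ends (SPO11-RI, SPO11cc and double-cut ends), each retained with its
      own detection efficiency (default 1.0).
    * ``ExoT_only`` — blunts only protein-free overhangs: every SPO11-bound
      central endpoint is lost.
    * ``TDP2_ExoT`` — TDP2 hydrolyses the phosphotyrosyl adduct of blunt
      SPO11 cleavage complexes (including double-cut ends) but is inactive on
      SPO11-RI, which is therefore lost.
    * ``MRN_CtIP_pre`` — in-vitro MRN+CtIP pretreatment nucleolytically
      removes SPO11-bound central ends with probability ``mrn_efficiency``
      before the standard ExoVII+ExoT workup.
    """
    if condition not in ENZYME_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {ENZYME_CONDITIONS}")
    if "species" not in track.data.columns:
        raise ValueError("track carries no per-endpoint species flags")
    rng = np.random.default_rng(0) if rng is None else rng
    df = track.data
    species = df["species"].to_numpy()
    keep = np.ones(len(df), dtype=bool)

    if condition == "MRN_CtIP_pre":
        bound = np.isin(species, list(SPECIES_BOUND))
        keep &= ~(bound & (rng.random(len(df)) < mrn_efficiency))
        condition = "ExoVII_ExoT"

    if condition == "ExoT_only":
        keep &= np.isin(species, list(SPECIES_FREE))
    elif condition == "TDP2_ExoT":
        keep &= np.isin(species, list(SPECIES_FREE | {"spo11_cc", "double_cut"}))
    else:  # ExoVII_ExoT
        eff = efficiency or {}
        for sp, e in eff.items():
            if e < 1.0:
                mask = species == sp
                keep &= ~(mask & (rng.random(len(df)) >= e))

    return EndpointTrack(df[keep].reset_index(drop=True), dict(track.genome))


# ---------------------------------------------------------------------------
# genotype presets
# ---------------------------------------------------------------------------

#: WT long-range gamma calibrated (truth-level Monte Carlo) so that at the
#: preset depth the generating distribution reproduces the wild-type
#: genome-wide statistics: median per-hotspot mean resection 1129 nt and
#: mean per-hotspot maximum endpoint 1845 nt.
_WT = dict(
    n_hotspots=2000, heat_rate=None,
    p_resected=0.89, p_ri=0.10, p_cc=0.01, p_doublecut=0.0,
    displacement=30.0, gap_mean=500.0, gap_sd=50.0,
    long_family="gamma", long_mean=629.0, long_sd=153.0,
    n_cells=30000, breaks_per_cell=200.0, spike_fraction=0.02,
    doublecut_low=40, doublecut_high=60,
)

_PRESETS: dict[str, dict] = {
    "WT": _WT,
    # ATM-null: 4.5x total breaks, SPO11cc and double-cutting dominate the
    # central signal, SPO11-RI essentially absent, hyper-resection, reads
    # within the WT gap region (smaller, more variable gap edge).
    "Atm": {**_WT, "breaks_per_cell": 900.0,
            "p_resected": 0.45, "p_ri": 0.0, "p_cc": 0.30, "p_doublecut": 0.25,
            "displacement": 0.0, "gap_mean": 300.0, "gap_sd": 150.0,
            "long_mean": 1700.0, "long_sd": 520.0},
    # DMC1-null: no homolog engagement, hence no SPO11-RI; both minimum
    # (gap +~400 nt) and maximum resection inflated.
    "Dmc1": {**_WT, "p_resected": 0.99, "p_ri": 0.0,
             "gap_mean": 900.0, "long_mean": 700.0, "long_sd": 170.0},
    # EXO1-null: long-range resection largely intact, slightly reduced
    # (median tract 996 vs 1129 nt).
    "Exo1": {**_WT, "long_mean": 496.0, "long_sd": 121.0},
    # PRDM9-null: no motif barrier, hence no SPO11-RI.
    "Prdm9": {**_WT, "p_resected": 0.98, "p_ri": 0.0, "p_cc": 0.01},
    # B6xCAST hybrid: asymmetric PRDM9 binding strongly reduces SPO11-RI.
    "hybrid": {**_WT, "p_resected": 0.97, "p_ri": 0.02, "p_cc": 0.01},
}


def preset(name: str, **overrides) -> TruthParameters:
    """Documented genotype parameter sets (WT, Atm, Dmc1, Exo1, Prdm9, hybrid)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return TruthParameters(**params)
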