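# Methods

## Coordinate and data model

All genomic coordinates are 0-based, half-open (BED-native); conversions
happen only at file boundaries.  The unit observation is the adapter-ligated
read 5′ endpoint: a `(chrom, pos, strand, weight)` record.  Duplicates are
kept throughout (peak calling with all duplicates retained), and the library
size is the weighted record count.  Side profiles index intensity by
distance from the hotspot center; bin *i* (1-based, width *b*) covers
distances `[(i−1)b, ib)` and is represented by its midpoint `ib − b/2`
(midpoint vs edge is a ≤ b/2 convention choice).

## Generative model of an END-seq library

Each hotspot receives Poisson-distributed break events (optionally weighted
by an exponential heat); every event emits exactly one top-strand and one
bottom-strand endpoint according to its processing category:

| category    | top strand            | bottom strand        | species flags |
|-------------|-----------------------|----------------------|---------------|
| resected    | cut + R_right         | cut − R_left         | free / free   |
| spo11_ri    | cut (if cut ≤ center) | cut − R_left         | bound / free  |
| spo11_cc    | cut + 1               | cut − 1              | bound / bound |
| double_cut  | right cut c₂          | left cut c₁          | bound / bound |

(For spo11_ri with the cut right of center the roles of the strands swap:
the motif-proximal end is always the blocked one.)  SPO11 cuts are displaced
from the hotspot center by a fixed magnitude *d* (default 30 bp) with random
sign, which produces the −2*d* = −60 nt reversed-polarity shift of SPO11-RI
central reads and leaves correct polarity for everything else.  Double-cut
spacing is uniform on [40, 60] bp, so the strand gap estimator reads ~+50 bp
on a pure double-cut library.

Resection endpoint distances are `gap + long`, with `gap ~ Normal(500, 50)`
clipped at 50 bp (the minimum-resection edge; its per-side split from the
published total gap width is a free parameter chosen so the population
minimum sits near 600 nt) and `long` gamma-distributed (positive,
right-skewed, matching the 1–3 kb endpoint spread; a lognormal family is
available).  Spike-in control cells are mixed in at an exact known fraction
(default 2%) and each contributes one blunt two-ended break at a dedicated
locus — the count is deterministic because the mixing ratio of control cells
is known, not sampled.  Uniform background endpoints are Poisson per strand.
A fixed seed gives byte-identical output, and every emitted endpoint is
reproducible from the returned truth table.

## Wild-type preset calibration

The WT preset is calibrated **at truth level** (from the generator's truth
table, never through the estimators) so that the generating distribution
reproduces the wild-type genome-wide statistics: median per-hotspot mean
resection 1129 nt (fixes `gap_mean + long_mean = 1129`) and mean per-hotspot
maximum endpoint 1845 nt (fixes the gamma sd, `long_sd = 153`, at the preset
depth).  Depth matters for the second statistic — the expected per-hotspot
maximum grows with the number of endpoint draws — so the preset's depth is
part of the calibration: ~3000 break events per hotspot (30 000
cell-equivalents × 200 breaks per cell over 2000 hotspots), reflecting that
deeply sequenced libraries carry thousands of reads at the strongest
hotspots.  Genotype presets modify this base: ATM-null (4.5× breaks,
central signal dominated by SPO11cc and double cuts, hyper-resection,
reads inside the wild-type gap), DMC1-null (no SPO11-RI, gap widened by
400 nt, inflated maxima), EXO1-null (long-range mean reduced 1129 → 996 nt),
PRDM9-null and B6×CAST hybrid (SPO11-RI absent or strongly reduced).

Category probabilities are per break event.  Because an SPO11-RI event
emits one central and one distal end, the *signal* share of central reads
in the WT preset is (p_ri + 2 p_cc)/2 = 6% of endpoints; the published-scale
fractions (11%/1.7%/…) enter the decomposition arithmetic as explicit
inputs rather than through the preset, and tests against simulated
libraries assert the model-implied value.

## Estimators: numerical choices

- **E(x)**: scale-invariant by construction (pᵢ normalization); sides with
  zero mass over bins 21–400 are undefined.  Undefined estimates propagate
  as NaN, never zeros.
- **Long-range peak**: argmax of the Gaussian-smoothed (50 bp span) side
  profile beyond 300 bp, leftmost tie.  The smoothing span keeps a delta's
  argmax at its own offset.
- **Minimum resection**: the ±500 bp region around the peak supplies the
  reference mean μ (a reference sample, not a search range).  Window width
  is 5 bins — the smallest width at which the t test has stable degrees of
  freedom while keeping boundary quantization at ~50 bp.  Zero-variance
  windows are decided by their common value (below μ ⇒ p = 0, otherwise
  p = 1), since the t statistic is undefined there.  The scan takes the
  first significant window sliding inward; only fully contained windows are
  evaluated.
- **Maximum resection**: dynamic background = max 20-bp bin at 5–6 kb on
  that side; the scan stops at the first window with more than half its
  bins at or below background, and the estimate is the last bin above
  background among all scanned bins **including the terminating window** —
  this matches the "last bin with detectable signal" reading and recovers
  the foot of a triangular profile to within one bin.  Profiles whose peak
  does not clear the background are undefined.
- **Genotype comparison**: one-sample t test on paired per-hotspot
  differences against a null offset (default 10 nt, the replicate-noise
  scale), H₁: mean difference > offset; unequal hotspot sets are restricted
  to the shared index with a warning.
- **Height matching**: the scale factor equates pooled-strand flank maxima
  over |offset| ∈ [800, 3000] bp (flank area is available as an option);
  matching is idempotent.  Central fraction clips negative per-offset
  differences at zero so flank sampling noise cannot create negative
  central mass, and warns if the unclipped negative excess exceeds 10% of
  the area.
- **Polarity shift**: location(top) − location(bottom) over the central
  window (±300 bp), using the smoothed-profile argmax (leftmost tie) or the
  intensity-weighted median; the median is the robust choice when strand
  distributions are flat-topped (uniform double-cut spacing).
- **Peak calling**: a deliberately simple fold-enrichment window scanner
  (2 kb windows, half-window step, pooled strands, uniform genome-wide
  expectation, >2.5-fold kept, blacklist removed; summit = leftmost argmax
  of 50-bp-smoothed per-base signal; score = best-window enrichment).  It is
  *not* equivalent to a local-lambda Poisson caller and is intended as a
  deterministic, testable stand-in.  The 2 kb window mirrors the ~2 kb
  strand separation that motivates shifted-tag peak calling on this assay.
- **Cross-correlation QC**: Pearson correlation of 10-bp-binned strand
  coverages with the bottom strand shifted, pooled across chromosomes.  The
  fragment peak is the maximum at negative shifts (END-seq polarity: top
  strand signal lies right of bottom strand), the read peak the maximum at
  positive shifts, and the baseline CCmin is floored at zero — sparse,
  nearly background-free synthetic coverage can dip the curve slightly
  negative, where the enrichment ratio NSC = CCfrag/CCmin loses meaning
  (NSC is reported as infinity when the baseline is exactly zero).
  Thresholds default to NSC ≥ 1.05 and RSC ≥ 0.8 (an NSC ≥ 1.5 convention
  also exists; both are exposed in the config).

## What the simulator does and does not emulate

It reproduces the geometry of the assay — strand conventions, the read-less
gap, protein-bound species and their enzyme-condition susceptibilities
(ExoVII+ExoT detects everything; ExoT-only detects only protein-free ends;
TDP2+ExoT additionally recovers blunt SPO11cc and double-cut ends but not
SPO11-RI; MRN+CtIP pretreatment removes bound central ends with
configurable efficiency), spike-in mixing, and uniform background.  It does
not model sequences, alignment or mappability, nucleosome positioning
beyond the cut-displacement parameter, secondary SPO11 cut clustering as a
separate class, read-length artifacts (so the read-length CC peak of real
QC pipelines has no counterpart here, and RSC under the null is not
meaningful), allele-specific effects, or per-hotspot covariates such as gene
expression.  Passing recovery tests therefore demonstrates estimator
correctness on the assay's geometry, not robustness to alignment or
chromatin artifacts in real libraries.

## Problem sizes

Tests run scaled-down simulations (50–500 hotspots, tens to hundreds of
events each) chosen so each property is measured well above its sampling
noise; the resection-recovery check and the acceptance script use the full
calibrated preset (2000 hotspots, ~3000 events each, ~12 M endpoints).  The
estimator-vs-oracle suite checks exact equality between the vectorized
scans and literal brute-force window evaluation on >1000 random profiles
spanning unimodal, step, sparse-count and degenerate shapes.

## Known limitations

- The minimum-resection t-test boundary on smooth unimodal profiles sits
  partway down the inner slope (it fires as soon as a window is
  significantly below the peak-region mean), so it reads high relative to
  the true population minimum on gradual profiles; it is exact on
  step-like gaps.
- The maximum-resection scan is coverage-limited: where read density (not
  resection) ends the scan stops, biasing the estimate a few percent low
  even at the calibrated depth.
- The fold-enrichment caller has no local background model; closely spaced
  hotspots merge into single peaks.
- decompose()'s `total_breaks_ref` (the denominator turning the implied
  SPO11cc count into a fraction) defaults to 333, the reference total
  implied by a ~2-break SPO11cc count at a 0.6% fraction; it is an explicit
  input because the assay does not fix it internally.
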