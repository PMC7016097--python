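"""Call DSB hotspots from a simulated library and compute signal-to-noise QC.

Runs the fold-enrichment caller against the simulated truth, then FRiP and
the strand cross-correlation profile with NSC/RSC.  END-seq polarity puts
the fragment-length correlation peak at a *negative* shift whose magnitude
matches twice the typical resection distance.
"""

import numpy as np

from endresect import (call_hotspots, cross_correlation, frip, preset,
                       simulate_library, truth_hotspots)

params = preset("WT", n_hotspots=150, n_cells=1500,
                genome={"chr1": 8_000_000, "chrS": 200_000},
                background_rate=2e-4, seed=2)
track, _ = simulate_library(params)

called = call_hotspots(track, window=2000, min_fold=2.5)
truth = truth_hotspots(params)
mids = ((called.data["start"] + called.data["end"]) // 2).to_numpy()
near = sum(np.abs(mids[called.data["chrom"] == "chr1"] - c).min() <= 1000
           for c in truth.data["center"])
print(f"called {len(called)} peaks at >2.5-fold enrichment; "
      f"{near}/{len(truth)} true hotspots recovered within 1 kb")

frip_value = frip(track, called)
qc = cross_correlation(track, shift_range=(-3500, 300), frip_value=frip_value)
print(f"FRiP = {frip_value:.3f} (ENCODE guideline: > 0.01)")
print(f"fragment shift = {qc.fragment_shift:+.0f} bp (negative = END-seq polarity)")
print(f"NSC = {qc.nsc:.2f}, RSC = {qc.rsc:.2f}, pass = {qc.passed}")
print("The |fragment shift| approximates the distance between the two")
print("long-range resection peaks flanking the cut sites.  In a nearly")
print("background-free simulation the baseline CC is ~0, so NSC (signal")
print("over baseline) degenerates to infinity; real libraries sit lower.")
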