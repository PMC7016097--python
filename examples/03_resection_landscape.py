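"""Quantify minimum, mean and maximum resection per hotspot and side.

Estimates the three per-hotspot resection statistics on a wild-type library,
prints the genome-wide summary, and compares mean resection against an
EXO1-null library with the offset t test (null shift mu = 10 nt, the
replicate-noise scale).
"""

import pandas as pd

from endresect import (bin_endpoints, compare_resection, estimate_resection,
                       preset, simulate_library, summarize_resection,
                       truth_hotspots)

tables = {}
for name in ("WT", "Exo1"):
    p = preset(name, n_hotspots=250, n_cells=2500, seed=3)
    track, _ = simulate_library(p)
    hs = truth_hotspots(p)
    m10 = bin_endpoints(track, hs, 4000, 10)
    m20 = bin_endpoints(track, hs, 6000, 20)
    tables[name] = estimate_resection(m10, m20)

print("WT genome-wide resection summary (bp):")
print(summarize_resection(tables["WT"]).round(0).to_string())

a = tables["WT"].set_index(["hotspot", "side"])["mean_resection"]
b = tables["Exo1"].set_index(["hotspot", "side"])["mean_resection"]
test = compare_resection(b, a, mu_offset=10)  # H1: WT - Exo1 > 10 nt
print(f"\nWT vs Exo1 mean resection: median difference "
      f"{test['median_diff']:.0f} nt, p = {test['p']:.2e} (mu = 10)")
print("A positive, significant difference reproduces the mild loss of")
print("long-range resection when EXO1 is absent.")
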