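"""Bulk genome scan: three LMM algorithms on one simulated population.

Simulates 30 inbred strains genotyped twice each (n=60) with a single QTL,
runs the exact, null-grid and alt-grid scans, and prints the top marker
per method.  The LOD score is the base-10 log-likelihood ratio of the
marker model against the no-marker null; larger means stronger evidence.
"""

import numpy as np

from bulkscan import (
    HeritabilityGrid,
    SimulationConfig,
    scan_alt_grid,
    scan_null_exact,
    scan_null_grid,
    simulate_dataset,
)

cfg = SimulationConfig(
    n_strains=30,
    replicates_per_strain=2,
    n_markers=40,
    n_traits=5,
    h2_true=0.4,
    qtl_positions=[10],   # causal marker index
    qtl_effects=[1.0],    # in background-SD units
    noise_seed=3,
)
Y, G, K = simulate_dataset(cfg)
print(f"simulated n={Y.n} individuals, m={Y.m} traits, p={G.p} markers; "
      f"QTL at marker 10")

grid = HeritabilityGrid.default()  # 0.0, 0.1, ..., 0.9
for name, result in [
    ("null-exact", scan_null_exact(Y, G, K)),
    ("null-grid ", scan_null_grid(Y, G, K, grid=grid)),
    ("alt-grid  ", scan_alt_grid(Y, G, K, grid=grid)),
]:
    lod = result.lod_values
    j = int(lod[0].argmax())
    print(f"{name}: trait 0 peak LOD {lod[0, j]:.3f} at marker {j}, "
          f"null h2 estimate {result.h2_null[0]:.3f}")

print("All three methods should localize the QTL at marker 10; the exact "
      "and grid methods differ only by the grid's h2 resolution.")
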