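#!/usr/bin/env python
"""Three-region safeguard phase diagram under pulsed medium dosing.

Scans the antibiotic (I_a) and nutrient (I_s) concentrations of the pulsed
fresh medium on a 20x20 grid with the full two-compartment BlaM model.  Each
row (fixed I_s) splits into three contiguous bands with increasing I_a:
no safeguard (growth in capsule and chamber), safeguard (growth only in the
capsule) and extinction; the safeguard band narrows as the nutrient feed
rises because faster-growing cells lyse more readily.  Writes
results/phase_diagram.csv (+ .meta.json).
"""

import time
from pathlib import Path

from swarmsafe.safeguard import DEFAULT_I_A_AXIS, DEFAULT_I_S_AXIS, scan_heatmap

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

t0 = time.perf_counter()
grid = scan_heatmap(DEFAULT_I_A_AXIS, DEFAULT_I_S_AXIS, horizon=16.0,
                    rtol=1e-6, atol=1e-9, progress=True)
grid.to_csv(OUT / "phase_diagram.csv")

code = {"no_safeguard": "N", "safeguard": "S", "extinction": "E", "failed": "?"}
print(f"\nscan of {grid.auc_matrix.size} cells in {time.perf_counter() - t0:.0f}s; "
      f"I_a rightwards from {grid.i_a_values[0]:.2f} to {grid.i_a_values[-1]:.2f}:")
for i_s, row in zip(grid.i_s_values, grid.region_matrix):
    print(f"  I_s={i_s:5.2f}  {''.join(code[r] for r in row)}")
widths = [sum(r == "safeguard" for r in row) for row in grid.region_matrix]
print(f"safeguard band widths (cells): {widths}")
print(f"wrote {OUT / 'phase_diagram.csv'}")
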