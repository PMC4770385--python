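#!/usr/bin/env python
"""Safeguard effectiveness versus the chamber/capsule volume ratio V_R.

Two-compartment collective-survival model, capsule seeded at 0.1 with an
empty chamber: at small V_R escaped cells re-establish a dense population
(no safeguard); past a transition the chamber never recovers and the AUC of
Delta-N keeps growing with the horizon (diverging flag).  Writes
results/auc_vs_vr.csv.
"""

from pathlib import Path

import numpy as np

from swarmsafe.models import SimplifiedParams, TwoCompartmentSimplifiedParams
from swarmsafe.safeguard import auc_vs_vr

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

params = TwoCompartmentSimplifiedParams(
    base=SimplifiedParams(mu=1.75, n_max=1.0, death_max=2.0, survival_k=0.01, hill_alpha=4.0),
    f_n_cells=0.1,
)
ladder = list(np.geomspace(1, 1e5, 11))
sweep = auc_vs_vr(ladder, params, initial=(0.1, 0.0))
sweep.to_csv(OUT / "auc_vs_vr.csv", index=False)
print(sweep.to_string(index=False))
first_div = sweep[sweep.diverging].v_ratio.min()
print(
    f"AUC is non-decreasing: {bool(np.all(np.diff(sweep.auc) >= -1e-9))}; "
    f"safeguard becomes persistent (diverging AUC) from V_R ~ {first_div:.3g}"
)
print(f"wrote {OUT / 'auc_vs_vr.csv'}")
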