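#!/usr/bin/env python
"""Fixed points of the collective-survival model and the N_CT-vs-K sweep.

With the reference parameter set (mu=1.75, Nm=1, d=2, K=0.5, alpha=4) the
model has three steady states: stable extinction at 0, the unstable
critical density N_CT, and a stable survival state.  Sweeping the survival
threshold parameter K traces how N_CT rises until survival becomes
impossible.  Writes results/steady_states.json and results/n_ct_vs_k.csv.
"""

import json
from pathlib import Path

import numpy as np

from swarmsafe.models import SimplifiedParams
from swarmsafe.steady_state import find_steady_states, n_ct_vs_k

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

params = SimplifiedParams(mu=1.75, n_max=1.0, death_max=2.0, survival_k=0.5, hill_alpha=4.0)
ss = find_steady_states(params)
print(f"steady states for {params}:")
for value, label in ss.states:
    print(f"  n* = {value:.6f}  ({label})")
print(f"critical density N_CT = {ss.n_ct:.6f}")
(OUT / "steady_states.json").write_text(json.dumps(ss.to_dict(), indent=2))

sweep = n_ct_vs_k(np.geomspace(0.01, 1.0, 40), params)
sweep.to_csv(OUT / "n_ct_vs_k.csv", index=False)
bistable = sweep[sweep.regime == "bistable"]
print(
    f"K sweep: bistable for K in [{bistable.K.min():.3g}, {bistable.K.max():.3g}], "
    f"N_CT rising from {bistable.n_ct.min():.4f} to {bistable.n_ct.max():.4f}"
)
print(f"wrote {OUT / 'steady_states.json'} and {OUT / 'n_ct_vs_k.csv'}")
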