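# swarmsafe

Population-dynamic models of **safeguard control for encapsulated engineered
bacteria** ("microbial swarmbots"): *E. coli* programmed for collective
survival are confined in a permeable hydrogel capsule, so the dense
population inside survives while cells escaping into the much larger
culture chamber fall below their survival threshold and die.

The package is organised as an analysis project: the library under
`src/swarmsafe/` holds every model and computation, the numbered scripts
under `analysis/` run the individual studies and write their tables to
`results/`.

## Models

**Collective survival** (one variable). Cell density N follows logistic
growth plus a death term that is repressed at high density:

    dN/dt = mu N (1 - N/N_m) - d K^alpha / (N^alpha + K^alpha) N

For suitable parameters there are three steady states — extinction (stable),
the critical density N_CT (unstable) and survival (stable) — so a population
persists iff it starts above N_CT. `steady_state` locates and classifies the
fixed points and sweeps N_CT against the threshold parameter K.

**Two-compartment extension.** Capsule (volume V1) and chamber (V2 = V_R·V1)
each follow the model above, coupled by gradient-driven cell escape
f_N (N_MSB − N_Out), the chamber receiving the flux scaled by 1/V_R.
Safeguard effectiveness is the area under ΔN(t) = N_MSB − N_Out
(`safeguard.auc_vs_vr`); AUC grows with V_R and becomes persistent
("diverges") once the chamber can no longer recover.

**Full BlaM circuit model.** Dimensionless densities of cells n, nutrient s,
antibiotic (carbenicillin) a and extracellular β-lactamase b:

    g = s/(1+s) (1-n)                      growth (Monod x logistic)
    l = max(sigma a/(1+a) (g - g0), 0)     lysis (only growing cells die)
    dn/dτ = g n - γ1 l n
    ds/dτ = -γ2 g n + β1 γ1 l n
    da/dτ = -b a/(1+a)
    db/dτ = -γ3 b + β2 γ1 l n

Lysis releases BlaM, which degrades the antibiotic — the collective-survival
feedback. The two-compartment version adds per-species transport
f_x (x2 − x1) across the capsule shell and square-wave pulsed dosing D(τ) of
the chamber with fresh medium carrying nutrient I_s and antibiotic I_a.
`safeguard.scan_heatmap` maps the (I_a, I_s) plane into the three safeguard
regions; `synthetic` + `fitting` provide a noisy-fluorescence observation
generator and least-squares parameter recovery.

## Worked example

```python
from swarmsafe import SimplifiedParams, find_steady_states, simulate

params = SimplifiedParams(mu=1.75, n_max=1.0, death_max=2.0,
                          survival_k=0.5, hill_alpha=4.0)
ss = find_steady_states(params)
for value, label in ss.states:
    print(f"n* = {value:.6f}  ({label})")
print(f"N_CT = {ss.n_ct:.6f}")

lo = simulate("simplified", [ss.n_ct * 0.99], params, horizon=500.0)
hi = simulate("simplified", [ss.n_ct * 1.01], params, horizon=500.0)
print(f"1% below threshold -> {lo.terminal[0]:.6f}")
print(f"1% above threshold -> {hi.terminal[0]:.6f}")
```

prints

```
n* = 0.000000  (stable)
n* = 0.564415  (unstable)
n* = 0.901005  (stable)
N_CT = 0.564415
1% below threshold -> 0.000000
1% above threshold -> 0.901005
```

i.e. the model is bistable with critical density N_CT ≈ 0.564: a population
seeded 1% below it collapses to extinction, 1% above it grows to the
survival state at ≈ 0.901.

The same models drive the analysis scripts:

```sh
python analysis/01_steady_states.py      # fixed points + N_CT vs K sweep
python analysis/02_volume_ratio_auc.py   # safeguard AUC vs volume ratio
python analysis/03_static_dynamics.py    # full model, no-flow conditions
python analysis/04_phase_diagram.py      # pulsed (I_a, I_s) region map
python analysis/05_parameter_recovery.py # synthetic data -> fit round trip
```

There is also a `swarmsafe` CLI (`simulate`, `steady-states`, `heatmap`,
`generate-data`, `fit`) driven by YAML configs; see `swarmsafe --help`.

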