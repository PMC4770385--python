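# Methods

## Models

### Collective survival

The one-variable model combines logistic growth with a density-repressed
death term,

dN/dt = μN(1 − N/N_m) − d·K^α/(N^α + K^α)·N,

where μ is the maximum growth rate, N_m the carrying capacity, d the
maximum per-capita death rate, K the survival threshold parameter and α the
Hill coefficient of the repression. The biology behind the death term is a
population-level rescue (quorum-regulated resistance or enzymatic
antibiotic degradation): killing is strong when the population is sparse
and shut off when it is dense. For d > μ the extinction state is stable and
for a window of K the system is bistable; the middle (unstable) fixed point
is the critical density N_CT. The reference parameter set used throughout
the analyses is μ = 1.75, N_m = 1, d = 2, K = 0.5, α = 4 (densities are in
units of the carrying capacity, time in units of 1/μ_max of the underlying
strain).

The two-compartment variant couples a capsule and a chamber, each with its
own logistic factor on its local density (no shared carrying capacity),
through gradient transport of cells: the capsule loses f_N(N_MSB − N_Out)
and the chamber gains that flux divided by the volume ratio V_R = V2/V1.
The volume-weighted total of every species is exactly conserved by the
transport terms, which the property tests verify to machine precision.

### Full BlaM circuit

The dimensional model tracks cell density N, nutrient S, carbenicillin A
and extracellular β-lactamase B. Growth G is Monod in S times logistic
crowding; lysis L = d_A·A/(K_lysis + A)·max(G/μ_max − G0/μ_max, 0) — the
max encodes that β-lactams only kill cells that are actively building wall,
so no lysis below the growth threshold. (The max wraps the whole product;
since the Michaelis–Menten factor is non-negative this equals applying it
to the growth excess alone.) Lysis releases BlaM (k_bla) and a fraction of
the cell's nutrients (k_r); BlaM decays (d_B) and degrades the antibiotic
with Michaelis–Menten kinetics (v_max, K_amp).

Non-dimensionalisation uses n = N/N_m, s = S/K_s, a = A/K_amp,
b = v_max·B/(μ_max·K_amp), τ = μ_max·t, and assumes K_lysis = K_amp so the
lysis saturation becomes a/(1+a). The groups are

γ1 = d_A/μ_max, γ2 = α·N_m/K_s, γ3 = d_B/μ_max,
β1 = k_r·N_m/K_s, β2 = k_bla·v_max·N_m/(μ_max·K_amp),

with the lysis efficiency σ kept as a separate dimensionless factor
(σ = 1 when converting from the dimensional form; the scaling of a by K_amp
versus K_lysis is degenerate with σ, so the conversion fixes one gauge).
The mapping is validated internally by a trajectory-equivalence test:
simulating the dimensional model and rescaling reproduces the dimensionless
trajectories to solver tolerance.

### Default dimensionless base values

The base set shipped with the package is

γ1 = 6.75, γ2 = 1.0, γ3 = 1.0, β1 = 0.2, β2 = 2.0, σ = 1.0, g0 = 0.1,

chosen once, before the analysis runs, to reproduce the qualitative
behaviour of the engineered strain:

* **Growth threshold near a ≈ 0.2.** At ample nutrient the net per-capita
  rate g − γ1·σ·a/(1+a)·(g − g0) changes sign at a ≈ 0.2, so sparse
  populations grow below that antibiotic level and die above it.
* **Bistable survival at a = 0.4.** The race between the lysis-driven BlaM
  burst (∝ β2·γ1·l·n, capacity ∝ initial density) and BlaM decay (γ3)
  determines whether the antibiotic is pushed below the growth threshold
  before the population collapses. γ3 = 1 makes the degradation capacity
  scale with the seeding density, giving a clean threshold in n0 (around
  0.15 at a = 0.4, s = 10); a much slower BlaM decay would let arbitrarily
  small populations eventually clear the antibiotic, destroying collective
  survival.
* **β2 = 0 (no BlaM release) is lethal at any density**, reproducing the
  control strain.

Transport rates reflect that a cell is orders of magnitude larger than the
molecules: f_n = 0.01 ≤ f_b = 0.1 ≤ f_a = 0.3 ≤ f_s = 0.5 (BlaM, a ~29 kDa
protein, moves slower than the small molecules). Default volume ratio
V_R = 10 for the full model — a single capsule in a device chamber — and
the printed two-compartment collective-survival analyses scan V_R
explicitly from 1 to 1e5.

## Dosing

Pulsed perfusion is modelled as a square-wave dilution D(τ) acting on the
chamber only: every chamber species is washed out at −D·x2 and nutrient and
antibiotic are replenished at +D·I_s, +D·I_a. Pulse windows are half-open
[k·period, k·period + duration). `DosingSchedule.from_flow` converts the
physical settings — 4 μl/min for 5 min of every 30 min into a ~20 μl device
— giving a during-pulse rate of 0.2/min and a time-averaged rate of 2/h.

A well-mixed chemostat at D = 2/h would wash out a strain growing slower
than 1/h, antibiotic or not; the experimental device avoids washout through
its geometry and the capsule acting as a reservoir, effects outside a
two-compartment ODE. The default dimensionless pulsing schedule
(`DosingSchedule.pulsing_default`) therefore keeps the experimental 1:6
duty cycle (period 0.5 τ, duration 1/12 τ) but a time-averaged rate of
0.2 per τ, low enough that the chamber population can outgrow the flow when
the feed carries no antibiotic — the regime the phase diagram explores.
Both the physical conversion and the dimensionless default are plain
configuration values.

## Analyses

* **Steady states** — dense sign scan (4096 points on [0, 1.05·N_m]) of the
  per-capita rate (dividing out the trivial root at 0), Brent refinement to
  1e-10, stability from a central-difference derivative of the rate;
  |derivative| < 1e-8 is reported as degenerate (saddle-node boundary)
  rather than silently classified. The test suite cross-checks against an
  independent 1e5-point grid scan + bisection oracle on 50 random sets.
* **Integration** — LSODA with rtol 1e-8 / atol 1e-10 by default (the lysis
  term and pulse discontinuities make the full model stiff); pulsed runs
  are segmented at every on/off boundary so the solver never steps across
  the discontinuity; output on 200 uniform samples plus the boundaries.
  Solver-induced negative values above −1e-9 are clamped to zero, anything
  below that magnitude raises. The heatmap and synthetic-data batch runs
  use rtol 1e-6 / atol 1e-9, which changes no region label (AUC agrees to
  well under the quadrature tolerance) at a quarter of the cost.
* **Safeguard metric** — ΔN = n_inside − n_outside on the trajectory grid,
  AUC by the trapezoid rule. Region from *terminal* densities with
  grow_threshold = 0.5·N_m: both above → no safeguard, only inside →
  safeguard, both below → extinction (outside-only growth counts as no
  safeguard: containment has failed). A safeguard run whose terminal ΔN is
  ≥ persist_threshold = 0.3 is flagged diverging — AUC grows without bound
  with the horizon, the decidable stand-in for "AUC approaches infinity".
  AUC is always reported over the simulation horizon together with that
  flag, rather than attempting integration to a steady state.
* **Phase diagram** — 20×20 grid, I_a ∈ [0, 1.2] linear, I_s ∈ [1.5, 10]
  geometric, horizon 16 τ, initial state n1 = 0.5, n2 = 0.01 (a pre-grown
  capsule plus a few already-escaped cells), s and a equilibrated with the
  feed. The I_s floor of 1.5 keeps the chamber's pulsed-chemostat
  equilibrium density above the growth threshold when no antibiotic is fed,
  so the no-safeguard band exists along the whole axis; the I_a ceiling of
  1.2 reaches well into extinction at every nutrient level.
* **Synthetic observations** — density sampled every 0.5 τ (a ~30-min
  imaging cadence over a 16-h run), fluorescence gain 1, multiplicative
  lognormal noise with CV 5% (mean-preserving parameterisation), optional
  detection floor. Deterministic given (trajectory, noise model, seed);
  batch seeds derive from the master seed via a spawned seed sequence. The
  generator emulates noisy, regularly sampled per-compartment density
  proxies only — not image formation, optical crosstalk, bleaching or
  OD/fluorescence calibration — so passing recovery tests show the fitting
  machinery is sound, not that real microscopy data would be this clean.
* **Parameter recovery** — bounded multi-start least squares
  (`scipy.optimize.least_squares`, 8 log-uniform starts by default) on raw
  density residuals (observations can be censored to zero, so no log
  transform by default), trajectories simulated from the known seeding
  density. Along a single growth curve μ and K are almost perfectly
  correlated (ρ ≈ 0.997; the information analysis is in the test suite's
  design rationale), so the recovery study fits a tagged pair — one curve
  seeded above N_CT (n0 = 0.7) and one below (n0 = 0.4), 33 samples each —
  which decorrelates the pair and yields sub-2% RMSE at CV 5%. The Hill
  exponent, whose likelihood surface is nearly flat at low noise, is
  profiled on the grid {1, 2, 4, 8} before continuous refinement. With
  observations only from deep in the extinction branch the death term is
  saturated and K runs to its box bound — reported as is, not pinned.
  The 8-state full model is deliberately not fitted: it is not identifiable
  from density-only observations.

## Problem sizes

The analysis scripts and the acceptance run use: 21 bistable parameter sets
(the reference set plus 20 rejection-sampled ones) for the threshold-
dynamics check; 6–11 volume ratios spanning 1–1e5; a 400-cell phase
diagram; 20 noise replicates (×2 trajectories ×33 samples) for the
recovery study. Together they complete in a few minutes on one CPU.

## Known limitations

* The dimensionless base values are this package's documented calibration,
  not a published table; all of them are exposed in configuration and the
  acceptance surface is the qualitative structure (bistability, three
  ordered phase regions, band narrowing), not numeric curve overlap.
* Quorum-sensing circuits (QS-CAT, QS-BlaM) are represented only through
  the threshold parameter K of the collective-survival model, not
  mechanistically.
* No spatial resolution within the capsule or chamber (two well-mixed
  compartments), no stochastic demography — extinction is asymptotic decay,
  so "extinct" is judged against a 1e-3 density floor at a finite horizon.
* The static safeguard is transient by construction (finite antibiotic is
  eventually degraded); the time of chamber escape depends strongly on
  V_R and the transport rates.
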