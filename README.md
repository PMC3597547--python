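# tissuesim

Desk-scale simulation of multicellular tissue and cardiac electrophysiology
in one Python library: the five standard individual-cell-based modelling
paradigms — cellular automata, cellular Potts, off-lattice cell centres
with radius- or Delaunay-defined neighbours, and 2D vertex dynamics —
coupled to reaction–diffusion PDEs and per-cell signalling ODEs, plus a
monodomain cardiac tissue solver built on the Luo–Rudy 1991 ventricular
action-potential model with standard postprocessing (APD, conduction
velocity, pseudo-ECG).

It is written for modellers who want to study mechanisms — oxygen-limited
tumour-spheroid growth, monoclonal conversion in intestinal crypts,
Delta–Notch lateral inhibition, spiral-wave re-entry — on a laptop, with
every run exactly reproducible from a config file and a seed.

## The models

**Off-lattice cell centres.** Cells are points moving under overdamped
dynamics η dr/dt = Σ F with linear-spring pair forces
F = μ(|r| − s) r̂ (rest length s = 1 cell diameter, cutoff 1.5,
optionally repulsion-only). Neighbours come from an interaction radius
(node-based) or the Delaunay triangulation of the centres (mesh-based).

**Vertex dynamics.** Cells are polygons; vertices move down the exact
gradient of the tissue free energy
E = Σ_cells [K_A(A−A₀)² + K_P(P−P₀)²] + Σ_edges γℓ, with T1/T2
rearrangements.

**Cellular Potts.** Cells are lattice-site domains evolved by Metropolis
dynamics on H = Σ J(τᵢ,τⱼ)·[σᵢ≠σⱼ] + Σ λ(a−A)², acceptance
min(1, e^(−ΔH/T)).

**Cellular automata.** Lattice sites hold up to κ cells; migration and
division by random-sequential occupancy rules.

**Reaction–diffusion.** −∇·(D∇c) + kc = f solved with P1 finite elements
on simplex meshes (steady or implicit-Euler parabolic); used for
quasi-steady oxygen around growing cell populations.

**Monodomain cardiac tissue.** χC_m ∂V/∂t = ∇·(σ∇V) − χI_ion with the
eight-variable LR91 membrane model, solved by Godunov splitting:
Rush–Larsen gate updates per node, then an implicit diffusion step.
S1–S2 cross-field stimulation induces re-entrant spiral waves.

## Worked example

A stimulated ventricular action potential from rest:

```sh
tissuesim single-cell-ap --output-dir out -v
```

prints

```
rest V: -84.548 mV
APD90: 364.08 ms
```

The first line is the root-found quiescent equilibrium of the membrane
model (all gates at steady state, calcium balanced); the second is the
action-potential duration at 90% repolarization of the AP elicited by a
1 ms, −80 µA/cm² stimulus, measured between interpolated crossings of the
repolarization level — the standard single-cell summary statistic. The
full trace is written to `out/ap_trace.dat` (time in ms, voltage in mV).

Other built-in examples, each driven by a plain-text config and a seed:

```sh
tissuesim spheroid      --output-dir out  # oxygen-limited tumour growth
tissuesim crypt-villus  --output-dir out  # crypts + villus, clonal drift
tissuesim spiral        --output-dir out  # S1-S2 spiral-wave induction
tissuesim potts-demo    --output-dir out
tissuesim vertex-demo   --output-dir out
```

Outputs are legacy ASCII VTK files (viewable in ParaView), CSV cell
tables, and a log echoing the resolved config, so every run is
reproducible byte-for-byte from (config, seed). `--checkpoint-every`
writes JSON checkpoints that resume bit-identically.

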