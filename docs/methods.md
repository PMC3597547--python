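# Methods

This note documents the models implemented in `tissuesim`, the numerical
choices behind them, and what the synthetic study conditions do and do not
establish about real tissue.

## Scope and units

Two domains share one infrastructure (seeded randomness, fixed-step ODE
solving, P1 finite elements, VTK/CSV output, JSON checkpoints):

* **Cell-based tissue models** — lengths in cell diameters, times in hours.
* **Monodomain cardiac electrophysiology** — mV, ms, cm, uA/cm^2, mS/cm^2
  (membrane conductances), mS/cm (tissue conductivity), uF/cm^2, mM.

All solvers are serial and sized for a desktop: PDE meshes up to ~10^4
nodes solved by sparse direct factorization, cardiac sheets up to
121 x 121 nodes.

## Randomness and reproducibility

Every stochastic operation draws from a `RandomStream` wrapping numpy's
PCG64, pinned so a seed always maps to the same draw sequence.  Simulator
step times are computed as `base_time + k*dt` rather than accumulated, and
the generator state serializes exactly into checkpoints; together these
make a resumed run bit-identical to an uninterrupted one, which the test
suite asserts at the level of output file bytes.

## ODE solving

Explicit Euler and classical RK4 with a truncated final step; both orders
are verified against closed-form linear systems.  Event termination
brackets the first sign change of the event function over an accepted step
and bisects on the linearly interpolated trajectory to 1e-8 of a step.
Adaptive stiff solvers are deliberately not implemented; `scipy`'s LSODA
appears only as an independent reference in tests.

## Finite elements

Linear (P1) simplex elements in 2D/3D assembled into stiffness and
consistent mass matrices; Dirichlet rows eliminated symmetrically;
zero-flux is the natural condition.  Steady reaction-diffusion
(-div(D grad c) + k c = f) and implicit-Euler parabolic stepping share the
assembly.  Verified: exact reproduction of linear fields, the parabolic
(constant-uptake) and modified-Bessel (linear-uptake) radial profiles on a
disc to <1% L2 at ~5k nodes, observed convergence order ~2, a discrete
maximum principle on the acute-triangle disc fixtures, and non-negativity
for non-negative data.  Point evaluation is barycentric inside the mesh's
own containing element (located via a centroid KD-tree), not a fresh
triangulation, so tie meshes interpolate consistently.

## Cell-based paradigms

**Cell centres (node- and mesh-based).**  Overdamped dynamics
`eta dr/dt = sum F` with forward Euler (default dt = 1/120 h, eta = 1) and
an instability guard at 0.5 diameters/step.  The pair force is a linear
spring of stiffness mu = 15 (force per unit length, nondimensional), rest
length 1 diameter, cutoff 1.5; a repulsion-only variant clamps attraction
to zero.  Neighbours are either all pairs within an interaction radius
(node-based, cKDTree) or pairs sharing a Delaunay element (mesh-based,
retriangulated lazily after every move).  After a division the daughter is
placed 0.3 diameters away in a uniformly random direction and the
parent-daughter rest length ramps linearly from 0.3 to 1 over 1 h; the
ramp applies only to that pair.  Coincident centres are repelled along a
seeded-random direction with magnitude mu*s — a documented, reproducible
degenerate-case rule.

**Cycle models.**  Fixed duration; uniform stochastic duration (drawn per
cell from the population's stream); and an oxygen-dependent model that
cycles strictly above c_quiescent = 0.7, arrests (age frozen) in
(c_death, c_quiescent], and accumulates a death timer at or below
c_death = 0.3, killing after tau_death = 2 h of sustained exposure (timer
resets on recovery).  All thresholds treat ties as the inactive state.
Initial populations desynchronize by drawing the starting age uniformly
in [0, duration).

**Cellular automaton.**  Lattice sites hold up to kappa cells (default 1,
exclusion).  Migration is random-sequential: each cell in shuffled order
proposes a uniformly chosen von-Neumann neighbour and moves iff spare
capacity exists.  Division places the daughter in a uniformly chosen
neighbouring site with spare capacity and is skipped (not forfeited) when
none exists.

**Cellular Potts.**  2D spin lattice, medium spin -1, Hamiltonian
`H = sum_{unequal-spin neighbour pairs} J(type_i, type_j)
   + sum_cells lambda (a - A)^2`
with von-Neumann neighbourhood by default and no perimeter term.  One
Monte-Carlo sweep is N_sites elementary moves: copy a random neighbour's
spin into a random site, accepted with probability min(1, exp(-dH/T))
(T = 0 accepts iff dH <= 0); a move that would erase a cell's last site is
rejected.  dH is computed incrementally and verified against full
recomputation; the acceptance rule is calibrated against exp(-1) at
dH = 1, T = 1.

**Vertex dynamics (2D).**  Tissue free energy
`E = sum_cells [K_A (A - A0)^2 + K_P (P - P0)^2] + sum_edges gamma * L`
with per-edge adhesion (boundary vs interior).  Vertex forces are the
exact analytic negative gradient assembled from shoelace area and
perimeter shape gradients, verified against central differences to 1e-5.
T1 swaps trigger when an interior edge falls below 0.01*sqrt(A0) and
re-expand perpendicular at 1.5x the threshold; T2 removal deletes
triangles below 0.001*A0.  Cell division splits the polygon by the line
through its centroid perpendicular to the long axis of its vertex cloud
(areas conserved to 1e-9).

**Engine.**  The per-step event order is fixed:
(1) cycle/oxygen/Wnt update, (2) signalling ODEs, (3) deaths/killers,
(4) divisions, (5) forces and movement (+ surface projection),
(6) PDE re-solve at the coupling interval, (7) scheduled output.
The order is part of the reproducibility contract since changing it
changes trajectories.

## Tumour spheroid (oxygen coupling)

Oxygen is quasi-steady: cell dynamics are hours, oxygen diffusion is
seconds, so the elliptic problem is re-solved at a coupling interval
(default 0.25 h in the shipped configuration) instead of time-stepping the
parabolic equation.  The boundary condition is a fixed concentration
(value 1) at the tissue surface, implemented by clamping every mesh node
that lies farther than 1 cell diameter from the nearest living cell and
beyond the colony extent (so an interior void left by dead cells is not
clamped — it is not bathed in oxygen); linear-in-c
uptake (k = 0.07 /h, D = 1 diam^2/h) is supported on elements whose
centroid lies within 0.75 diameters of a living cell.  With a ~200-cell
colony (radius ~7.4 diameters) these defaults put the 0.7 contour in the
outer fifth of the tissue and drive the centre below 0.3 as the colony
grows — a proliferating rim, a quiescent annulus, and a dying core.  The
uptake rate was chosen from the closed-form Bessel profile so that the
oxygen penetration depth sqrt(D/k) ~ 3.8 diameters is about half the
colony radius; it is a config knob, not a fitted constant.  The 2D disc
geometry is this package's desk-scale choice; the layering mechanism is
dimension-generic.

## Crypt-villus epithelium

Node-based cells in 3D confined to a parametric surface: a flat sheet
pierced by four crypts (test-tube shapes descending 3 diameters, radius 1,
on a ring of radius 3) around one central villus (ascending 4).  Closest-
point projection runs after every position update; exact medial-axis ties
resolve tube-before-plane, keeping projection deterministic and
idempotent.  Proliferation uses a position-dependent Wnt proxy
`wnt = clamp(1 - z/L, 0, 1)` (z = height above the crypt base), cycling
strictly above threshold 0.7 — a basal stem compartment.  Cells are
removed at the villus tip and at the sheet edge.  A small Brownian
motility term (sigma = 0.1 diam/sqrt(h), seeded) represents active cell
motion; without it cells cannot round the right-angle junction at the
villus base, and with it the villus populates from crypt outflow.
Intracellular Wnt reaction networks are intentionally replaced by this
positional rule.

Clonal dynamics: each initial cell founds a clone (`ancestor_id`,
inherited at division, never created anew — an asserted invariant).  Under
neutral competition each crypt drifts to monoclonality within a few
hundred hours.  The drift ensemble uses a reduced single-crypt geometry
(10 cells, 4 symmetric clones assigned round-robin to shuffled cells,
dt = 0.02 h) run to fixation 200 times; symmetry demands fixation
frequency 1/4 per clone, checked within binomial 3-sigma.

Newborn cells carry a reduced size: their repulsive contact length to any
neighbour grows from 0.3 to 1 diameter over the ramp hour, while
attraction engages only beyond the full rest length; the dedicated
parent-daughter ramp (0.3 -> 1) overrides this for that one pair.  This is
the overlapping-spheres reading of cell growth and keeps post-division
transients within the movement guard.

## Delta-Notch lateral inhibition

Per-cell two-variable system
`dn/dt = F(d_bar) - n`, `F(x) = x^k/(a + x^k)`;
`dd/dt = v (G(n) - d)`, `G(n) = 1/(1 + b n^h)`,
with d_bar the mean Delta of the cell's current neighbours (isolated
cells see 0).  Defaults a = 0.01, b = 100, v = 1, k = h = 2 — the standard
lateral-inhibition regime in which the homogeneous state is unstable.  The
tissue update is synchronous (d_bar frozen over each dt, RK4 per cell),
which makes the update order-independent.  The homogeneous fixed point is
found by bisection on d - G(F(d)); patterning is validated against a
numerically computed Jacobian of the two-cell system: perturbations of
1e-6 grow exactly when the fixed point is linearly unstable.  Patterned
sheets are summarized by the Pearson correlation of Delta across neighbour
pairs (negative = alternating pattern; all-equal Delta is an undefined-
correlation sentinel).  Daughters inherit the parent's signalling state.

## Cardiac electrophysiology

**Cell model.**  The eight-state guinea-pig ventricular action-potential
model (V; gates m, h, j, d, f, X; Cai) with its six membrane currents;
Nernst potentials computed from the model's ionic concentrations
(E_Na = +54.8 mV, E_K = -77.6 mV, E_K1 = E_Kp = -87.9 mV at Ko = 5.4 mM).
The quiescent equilibrium is root-found by bisection on total ionic
current with gates at steady state and calcium at its own balance,
landing at V = -84.5 mV; the split integrator holds it to <1e-3 mV over
100 ms.  Per-current conductance multipliers and per-gate rate scalings
(both alpha and beta, preserving steady states while shortening time
constants) support ion-channel-modification protocols.

**Numerics.**  Gates advance by the exponential (Rush-Larsen) update with
frozen rates, clamped to [0,1]; V and Cai by forward Euler; dt <= 0.1 ms
enforced, default 0.02 ms.  Single-cell APD90 differs from an adaptive
reference integrator by <0.1 ms at dt = 0.02 ms, and halving dt moves it
by <0.03%.

**Tissue.**  Monodomain `chi C_m dV/dt = div(sigma grad V) - chi I_ion`
with chi = 1400 /cm, C_m = 1 uF/cm^2, solved by Godunov splitting: the
cell step at every node (vectorized over the grid), then one implicit-
Euler diffusion step (5-point zero-flux Laplacian, prefactorized sparse
LU — unconditionally stable).  The diffusion substep conserves mean
voltage to 1e-10 and preserves 4-fold lattice symmetry to 1e-9.
Plane-wave conduction velocity at sigma = 1.75 mS/cm is ~0.064 cm/ms,
self-converging under (dx, dt) refinement to <5% at dx = 0.00625 cm.

**Spiral protocol.**  S1 excites the left edge at t = 0; S2 covers the
lower-left quadrant at a premature coupling interval (scanned over
70-100 ms when not pinned).  The "spiral" preset reduces the slow-inward
conductance to 0.1x and doubles the d/f gate rates, shortening APD90 to
~47 ms so the re-entrant wavelength fits a 3 x 3 cm sheet at
sigma = 0.7 mS/cm; this is a reconstruction of the published class of
ion-channel-modification protocols, and the test of success is
persistence of re-entry (any node above -20 mV at least two rotation
periods after stimulation ends), not trajectory matching.  S1 alone must
leave the sheet quiescent (all nodes below -60 mV) after one sweep.

**Postprocessing.**  APD_p between linearly interpolated crossings of
`V_peak - (p/100)(V_peak - V_rest)` with V_rest taken pre-stimulus;
activation time = first interpolated crossing of -40 mV; conduction
velocity two-point or by regression of activation time on distance;
pseudo-ECG `Phi = -k int grad V . grad(1/|x - x_e|) dx` by nodal
quadrature with the electrode required outside the tissue (verified
against the sign of a hand-worked cable discretization and the far-field
1/r^2 dipole decay).

## Output, configuration, checkpoints

Legacy ASCII VTK (header pinned, floats at 9 significant digits, no
timestamps) so identical states write identical bytes; CSV cell tables
with a fixed column order; atomic write-and-rename everywhere.
Configuration is flat `key = value` with dotted sections; unknown keys are
rejected and defaults are materialized into the echoed config, so
(echo, seed) fully determines a run.  Checkpoints are a versioned JSON
container holding cells, positions/lattice/polygons, cycle timers,
signalling states, the PDE field, the RNG state and the config echo.

## What the synthetic conditions do not show

The generators emulate idealized tissue: circular colonies, uniform cell
sizes, isotropic conductivity, no extracellular matrix, no mechanics
feedback on the cycle, and a positional Wnt proxy instead of pathway
dynamics.  Passing tests establish internal correctness (against closed
forms, brute-force oracles and reference integrators) and the qualitative
behaviours of the modelled mechanisms — rim-restricted growth, monoclonal
conversion, alternating Delta-Notch patterns, spiral re-entry — not
quantitative agreement with any particular experimental tissue.

## Problem sizes

The shipped study conditions are desk-scale: ~200-cell spheroids for 50 h,
~100-cell crypt-villus patches run to monoclonality, 10-cell drift crypts
(200-run ensembles), ~5k-node PDE discs, and 121 x 121 cardiac sheets for
a few hundred ms.  All were chosen as the smallest sizes at which the
phenomena of interest are unambiguous.
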