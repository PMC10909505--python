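# Methods

## Model

The tissue is a planar shared-vertex tessellation: cells are simple,
counter-clockwise polygons; interior junctions are tri-junctions; the tissue
boundary is free (no periodic box; boundary vertices obey the same equation
of motion with no extra term). The configuration energy is

    E(r) = Σ_α [ K/2 (A_α − A_α⁰(t))² + Γ/2 L_α² ] + Λ Σ_⟨ij⟩ l_ij ,

with per-cell area A_α and perimeter L_α, and the line-tension sum visiting
each *unordered* edge once (not once per cell side — variants differ here).
Vertices follow overdamped dynamics γ dr_i/dt = F_i = −∇_i E, integrated by
explicit forward Euler, r ← r + (dt/γ) F. With static targets, γ only
rescales time (τ = t/γ); this symmetry is exact for the integrator when dt
is scaled with γ, and the tests exploit it. The symmetry breaks as soon as
the cell cycle introduces its own timescale, which is the phenomenon this
package exists to study.

Each cell carries a stochastic intrinsic cycle length drawn at birth,

    t_c ~ ε·T_c + Exp(mean (1−ε)·T_c),    ⟨t_c⟩ = T_c ,

and a target-area schedule A⁰(age) = 1 for age < t_c/2, then min(2·age/t_c,
A_f): constant through the first half of the cycle, growing linearly to 2
at age t_c, clamped at A_f. The clamp is a modelling decision: the raw
schedule is unbounded past t_c, and a high-friction cell whose division is
blocked by the area gate would otherwise be driven elastically without
limit. Division requires age ≥ t_c AND (optionally) apical area ≥ A_c;
disabling the area gate is the "A_c = 0" model variant.

Division surgery splits the polygon by a line through its area centroid
along a uniformly random direction (a short-axis rule is not used; random
planes keep daughters statistically symmetric). One vertex is inserted on
each crossed edge — also into the neighbouring cell's loop, so
tri-junctions are preserved — and crossings are rejected if they would
create an edge shorter than `l_new` (absolute) or closer than 8% to an edge
endpoint (relative); up to 12 directions are tried before the division is
deferred a few steps. Daughters restart the schedule at A⁰ = 1 with fresh
independent t_c draws and inherit the parent id as lineage pointer.

## Topological transitions

T1: an interior edge shorter than `l_T1` whose endpoints are both full
tri-junctions is rotated 90° about its midpoint and rescaled to `l_new`;
the two sharing cells lose a side, the two flanking cells gain one. Edges
touching the free boundary never swap. T2: a three-sided cell with area
below `A_T2` collapses to a vertex at its centroid (each neighbour loses a
side); a boundary triangle without two interior sides is peeled off.

Inside the simulation loop T1 swaps are additionally *energy gated*: the
swap is rolled back if it would raise the energy of the four incident
cells. The gate is not cosmetic. The dynamics are purely relaxational, so
an energy-raising swap is immediately undone by the flow; without the gate,
junctions that the tissue wants to keep collapsed (a jammed, solid-phase
tissue produces many) enter a swap/unswap cycle every few steps, polluting
the T1 statistics with tens of thousands of events and dominating the
runtime. A rejected junction is left as a near-fourfold vertex (the edge
sits near zero length with bounded forces; unit vectors are clamped below
1e-12) and is re-examined after a cooldown of 1000 steps, or sooner when
divisions change its neighbourhood. If the two endpoints of such a
collapsed edge drift through each other the resulting micro-sliver is
repaired by swapping the endpoint positions (`untangle_collapsed_edges`),
applied before division surgery and at the end of a run. The bare,
ungated geometric T1 remains the public operation.

Thresholds (`l_T1 = 0.05`, `l_new = 0.06`, `A_T2 = 0.02`, in units where
the initial cell area is 1) are numerical-regularisation knobs, not
biophysical parameters; the qualitative results are insensitive to them.

## Parameters

Reference values (arbitrary units), used as defaults throughout:

| symbol | meaning                          | value |
|--------|----------------------------------|-------|
| K      | area elasticity                  | 1     |
| Λ      | line tension                     | 0.05  |
| Γ      | perimeter contractility          | 0.02  |
| A_f    | max target area of a mitotic cell| 2     |
| A_c    | critical division area           | 0.78·A_f = 1.56 |
| T_c    | mean intrinsic cycle duration    | 388   |
| ε      | deterministic cycle fraction     | 0.8   |
| γ      | friction coefficient             | swept: 0.01 … 2 |

The initial condition is a hexagonal lattice of 100 unit-area cells, all
born at t = 0 with independent t_c draws (no extra age desynchronisation).
The initial cell area is not separately specified by the study conditions;
it defaults to 1, the initial target area, and is a config option.

## Numerics

* Integrator: explicit forward Euler. Default dt = 0.05·γ/K. A linear
  stability estimate (top Hessian eigenvalue of the energy ≈ a few ×K for
  these parameters, spiked by short edges near the T1 threshold) puts the
  stability boundary near dt ≈ 0.5·γ/K; sweep-scale runs use dt = 0.1·γ/K,
  for which measured observables (mean area, division age) differ from the
  0.05·γ/K reference by ≈0.15%, far below replicate scatter, at half the
  cost. Because dt scales with γ, trajectories at different γ use the same
  dt/γ and are numerically equivalent in rescaled time.
* The inner loop is a numba kernel advancing the flat-array mesh until a
  snapshot time, a short edge, a small triangle or a division-ready cell
  needs Python-side surgery; event checks use the pre-step geometry (one
  step of lag, below any other discretisation error). Cell/vertex arrays
  are rebuilt only on topological change.
* One `numpy.random.Generator` seeded from the config drives all
  stochasticity (initial t_c draws, division planes, daughter t_c draws),
  making runs bit-reproducible. Replicate r at parameter index p of a sweep
  uses `SeedSequence([master, p, r])`.
* Euler–Lotka roots use bracketed Brent iteration on k ↦ E[e^(−kτ)] − 1/2,
  which is strictly decreasing from 1/2 at k = 0, so the root is unique;
  the empirical variant replaces the transform by the plain sample mean of
  e^(−kτ_i) (the Euler–Lotka integral under the empirical measure, no
  smoothing). The stationary age distribution is tabulated on a 20001-point
  grid out to where its tail mass falls below 1e-14 for CDF/inverse-CDF
  queries.
* The newborn-window estimator k = (#ages < δ)/(2δN) uses δ = 2% of T_c by
  default; the window is doubled (up to three times) if empty, and the
  attached bootstrap standard error (200 resamples) makes the O(δ)
  discretisation bias (~1–2% here) visible against sampling noise.

## What the generators emulate — and what they do not

The synthetic-data surface has two parts. The lattice generator produces
the idealised initial condition (perfectly regular, age-synchronised
tissue) the study prescribes; real epithelia are neither regular nor
synchronised, so early-time transients here are artificial, and growth-rate
fits exclude the first T_c. The branching process realises the intrinsic
cycle model with *no* cell–cell interaction: every cell divides exactly at
its drawn t_c. It is the exact stochastic counterpart of the closed-form
Euler–Lotka rate and therefore serves as the oracle for the growth-theory
estimators; by construction it cannot show mechanical feedback, which is
precisely the gap between its prediction and the vertex-model measurement
that the friction study quantifies. A caveat inherited from the
synchronised start: the age structure needs ~10 generations to reach the
stationary density, so stationarity checks sample at ≥12 T_c while growth
slopes are already clean after ~2 T_c.

## Desk-scale study sizes

At full scale this study calls for 20 replicates grown to 15 000 cells.
The package's acceptance-scale experiments use 5 replicates per friction value
grown from 100 to ~1000 cells (ablation runs to ~600), chosen so the full
sweep completes in minutes while the orderings of interest (division-age
shift, tissue-size ordering, T2 inflation without the area gate) are
unambiguous. Two consequences are quantitative. First, a 1000-cell tissue
is only ~4 T_c old and still carries division waves from the synchronised
start: the instantaneous mean apical area oscillates with period ~T_c and
amplitude of several percent, so friction comparisons use the cell-weighted
mean area *averaged over the last intrinsic cycle* of each run
(`mean_area_cycle` in the sweep tables) rather than a single snapshot.
Second, the high-friction effects are *collective* crowding effects whose
strength grows with tissue size: the mean-area reduction at ~1000 cells
sits below the full-scale value, and the T2-extrusion inflation of the
no-gate variant does not occur at all at this scale — compressed cells
stabilise as small 4–5-sided polygons whose edges stay well above the T1
threshold, so the side-loss cascade that precedes an extrusion never
starts. Reproducing the T2 ordering requires full-scale tissues.

## Known limitations

* Single cell type; uniform K, Γ, Λ; no Langevin noise on vertices; no
  size-dependent (non-uniform) friction.
* No T3 (contact-creation) transitions; boundary junctions never T1-swap,
  so the free boundary can keep sub-threshold edges.
* Energy-gated T1s mean the simulated tissue can maintain near-fourfold
  vertices; vertex models that force every short edge to swap will report
  higher T1 counts in jammed states.
* The division-plane rule is random-through-centroid; Lewis-law-type
  statistics are known to depend mildly on this choice.
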