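# Methods

## Model

`epivertex` simulates a confluent epithelial monolayer as a two-dimensional
vertex model: the apical plane is a polygonal tiling, each cell a polygon,
each junction shared by two cells, and vertices (where three junctions meet)
are the dynamical degrees of freedom.  The mechanical energy is

    E = sum_c [ K_A/2 (A_c - A_c0)^2 + K_P/2 (P_c - P_c0)^2 ],

where `A_c`, `P_c` are the cell's area and perimeter and `A_c0`, `P_c0` its
targets.  The area term models volume conservation at preferred cell height;
the perimeter term models the contractile/adhesive junction belt.  The
target shape index `p0 = P_c0 / sqrt(A_c0)` controls solid-vs-fluid tissue
behaviour; the regular-hexagon value 6/sqrt(3*sqrt(3)/2) ≈ 3.722 and the
regular-pentagon value ≈ 3.81 bracket the classical rigidity transition.

Vertices follow overdamped dynamics `zeta * dr/dt = F = -grad E`,
integrated with the first-order Euler method.  No thermal noise term is
included; substrate friction is the only dissipation.  Forces are analytic:
the shoelace area gradient plus junction unit vectors for the perimeter
term (a central-finite-difference oracle verifies them to 1e-6 in the test
suite).  Clamped vertices are force-projected to zero, giving exact
immobility.

A central `L_a x L_a` patch of *active* cells (they grow, divide, ingress)
is embedded in *passive* tissue clamped to the walls of an `L x L` box.
Passive cells deform and rearrange but have fixed targets.

## Cellular processes

* **T1 intercalation** — any interior junction shorter than `ell_T1` is
  rotated 90 degrees about its midpoint, re-opened at `1.02 * ell_T1`, and
  the four surrounding cells exchange neighbours.  Several simultaneously
  short junctions are processed in ascending length order; junctions whose
  endpoints already moved in the same sweep wait for the next step.
* **Growth** — active targets inflate linearly, `dA_c0/dt = g`, with
  `P_c0 = p0_a * sqrt(A_c0)` keeping the target shape index fixed.
* **Division** — evaluated once every `event_check_interval` (default 5)
  steps with logistic probability `1/(1 + exp(-alpha (A_c - A_d)))`.
  Division follows Hertwig's rule: the cut passes through the area centroid
  perpendicular to the long axis (principal eigenvector of the gyration
  tensor of the cell's vertices; an isotropic cell draws a random axis).
  Daughters re-draw their target perimeter from N(mu, sigma).
* **Ingression (T2)** — logistic probability `1/(1 + exp(beta (A_c -
  A_i)))`, evaluated on the same cadence after divisions (cells that divided
  in the current sweep, and their daughters, are exempt until the next
  sweep).  The cell collapses to a single vertex at its centroid; the
  resulting high-coordination vertex is resolved by repeated random
  admissible cuts into 3-valent vertices, each new junction opened at
  `1.02 * ell_T1`.
* **Type conversion** — a cell whose neighbours are all of the opposite
  type flips type (a passive cell that turns active draws fresh targets).

`A_d = 1.6 * mean` and `A_i = 0.3 * mean` active-cell area measured once at
the end of the passive relaxation and frozen.

## Parameters (simulation units)

| symbol | meaning | default |
|---|---|---|
| K_A | area modulus | 3.0 |
| K_P | perimeter modulus (energy scale) | 1.0 |
| zeta | friction | 1.0 |
| g | target-area growth rate | 2e-3 |
| alpha / beta | division / ingression steepness | 8.0 / 6.0 |
| ell_T1 | T1 trigger length | 5e-3 |
| dt | Euler step | 5e-3 |
| t_rel | passive relaxation time | 50 |
| mu, sigma | active target-perimeter distribution | 5.98, 0.3 |
| p0_a, p0_p | target shape indices | 3.600-3.825 |

`dt`, `ell_T1` and `K_A` trade numerical stability against run time;
`p0 > ~3.825` destabilises the simulation (irregular, overlapping cells),
which the driver reports as a first-class `unstable` outcome rather than a
crash.

## Initialization

Random seeds in the box are Lloyd-relaxed into a centroidal Voronoi tiling
(seeds moved to tile centroids until the maximum displacement per iteration
falls below `lloyd_tol * L`, default 5e-5).  Straight walls come from
mirroring seeds across each wall (and corner) within `mirror_cutoff`
(default `2L/sqrt(N)`, about two cell diameters); if an early iteration
still produces an unbounded tile the cutoff is doubled for that Voronoi
call only.  Wall vertices are snapped exactly onto the walls, and the wall
vertices plus `clamp_rings` (default 1) rings of neighbours are clamped —
the "outermost layers" attached to rigid surrounding tissue.  Cells whose
area centroid falls in the half-open centred patch square become active.

The half-edge (doubly connected edge list) mesh makes every topological
move a local pointer surgery with mechanical Euler bookkeeping
(V - E + F = 1 is asserted across a 10^4-operation randomized stress test).
Ids are tombstoned, never reused, so event logs stay valid across deaths.
Deterministic fixtures (regular honeycombs built on an exact integer
lattice, single-polygon cells) support the unit tests.

## Observables

Per sample (every 5 steps): active/passive counts and areas, fractional
changes `f_N = N_a(t)/N_a(t_ref)` and `f_A = A_a(t)/A_a(t_ref)` (the f_A
reference is a per-run flag: before or after relaxation, default after),
cumulative divisions and ingressions, per-type mean pressures
`-K_A (A_c - A_c0)`, the realised shape index `P_c/sqrt(A_c)` of active
cells (mean and population sd), and the neighbour-count histogram P_n.
Steady-state summaries are time means over a trailing window (default
Delta t = 500).  The exact ledger identity
`Sigma_d - Sigma_i + net_conversions = N_a(t) - N_a(t_ref)` holds at every
sample.

## Problem sizes used in the shipped tests and acceptance script

Full-scale runs of the source configuration (N = 1000, L = 50) take days of
CPU; the package's own verification uses scaled-down study conditions at
the same cell density L^2/N = 2.5:

* **Homeostasis runs** — N = 250, L = 25, L_a = 10 (~40 active cells),
  Table-defaults otherwise, t_end = 2000, averaging over t in [1500, 2000].
  These reach a clear homeostatic plateau (f_N ~ 1.9 at p0_a = 3.60,
  p0_p = 3.80) with ongoing balanced divisions and ingressions and a
  near-unity active/passive pressure ratio.
* **Parameter-trend sweeps** — N = 120, L = 17.32, L_a = 7, growth
  accelerated to g = 3e-3 to compress the approach to homeostasis,
  t_end = 1000, averaging over the final 200 time units, three seeds per
  point.

## What the scaled-down runs do and do not show

The generator emulates the study conditions at reduced size; it does not
add biological features absent from the model (cell-cycle structure,
biochemical signalling, internal dissipation, 3D effects).  At these sizes
the qualitative physics reproduces: saturation of f_N and f_A with
continuing turnover, pressure balance, the dominance of hexagons followed
by pentagons, and the trends of f_N with alpha, beta, g, p0_p and
confinement.  One full-scale result does **not** survive the reduction:
with only ~20-40 active cells, raising the active shape index p0_a (smaller
target cells) *increases* the steady cell count — more small cells simply
fit into the patch — whereas the full-scale study finds the opposite via
the softness/ingression mechanism.  The corresponding trend check and the
derived stiff-vs-soft gain-ratio check are therefore expected to fail at
desk scale and are retained as documentation of that limit.

## Numerical choices

* Geometric coincidence tolerance 1e-9 length units (division cuts within
  tolerance of a vertex reuse it; zero-length junctions contribute no
  perimeter force and are flagged for T1).
* A division is rejected (and logged) if the cut line does not cross the
  boundary at exactly two sites or would create a two-sided cell; a
  collapse is rejected if the cell touches a clamped vertex or the rim, or
  a neighbour would degenerate.  Rejected events are retried on later
  sweeps.
* One global seeded RNG per run; the draw order is fixed (initial seeds,
  target draws; then per event sweep: division uniforms, per-division axis
  and daughter-target draws, ingression uniforms, per-resolution cut
  draws, conversion target draws), so identical config + seed reproduces
  runs bit-for-bit.
* Sub-step order: Euler update -> T1 sweep -> growth -> divisions ->
  ingressions -> type conversions.  Population standard deviations divide
  by n.

## Known limitations

Curved junctions, periodic boundaries, 3D, self-propulsion, junction-level
tension dynamics and mechanosensitive growth feedback are out of scope.
The Euler integrator requires dt small enough that vertex displacements
stay below the T1 length scale; instability at aggressive parameters is
detected (non-positive cell area) and reported, not silently truncated.
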