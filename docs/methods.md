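# Methods

## Model and assumptions

The package simulates a two-species DNA predator-prey network in a closed
2-D reactor with impermeable walls. Prey N replicates autocatalytically
with saturating kinetics, the predator P grows by consuming prey (also
saturating), and both diffuse with unit diffusivity in mesh units:

    ∂t N = Cr·N/(1+bN) − Cp·N·P/(1+bP) − ε + ΔN
    ∂t P = Cp·N·P/(1+bP) − ε + ΔP

No physical length or concentration scale is imposed: coordinates are in
pixels of the source raster, the diffusion coefficient is 1, so wave
speeds are in pixels per unit time.

Two modelling points deserve emphasis.

* **The null state is regularized.** (N, P) = (0, 0) is linearly unstable
  for the prey; in floating point this lets round-off seed spurious growth
  far from any real concentration. The uniform decay ε (default 1e−13) is
  subtracted from both rates everywhere — even at zero concentration — and
  any resulting negative value is clamped to 0. Clamping is applied after
  *both* half-steps: negative entries in the state can also stall the
  conjugate-gradient solve.
* **The predator has no decay channel.** dP/dt ≥ −ε pointwise, so in a
  well-mixed volume the dynamics is a single excursion, not a limit
  cycle: from N = P = 1 the prey collapses once while the predator rises
  monotonically to a plateau. Spatially this is exactly what produces the
  single-pass traveling waves: prey spreads ahead by diffusion, the
  predator front follows and consumes it, and behind the front only
  predator remains. In dead ends the prey is cornered and driven to
  extinction.

## Discretization

**Geometry.** Reactors are binary rasters: synthetic perfect mazes
(recursive backtracker on a grid of corridor cells — guarantees a spanning
tree, hence full connectivity, no loops, and cul-de-sacs) or thresholded
grayscale images (intensity > 0.5 ⇒ interior). Multi-component reactors
are refused rather than silently simulated.

**Mesh.** Each open pixel is split into s×s sub-squares and each sub-square
into two right triangles. The diagonal alternates in a criss-cross pattern
(by sub-cell parity) so the discrete operator has no preferred diagonal
direction. Nodes are merged on shared pixel edges; ordering is lattice
row-major, so meshes are byte-reproducible. The subdivision s is the
resolution control — the structured analogue of a mesher's maximum cell
size. Uniform refinement only: corner-adaptive grading near the maze's
re-entrant corners would reduce the local discretization error there but
is not implemented.

**Matrices.** P1 element integrals are exact closed forms: the element
mass matrix is (area/12)·(J + I) and the element stiffness matrix
(bᵢbⱼ + cᵢcⱼ)/(4·area) with b, c the edge-vector components. Global D and
S are scatter-added in triangle order (deterministic duplicate summation)
and compressed. No boundary terms arise: the Neumann condition makes the
boundary integral of Green's identity vanish. S annihilates constants
(1ᵀS = 0), so it is positive semi-definite with a single zero eigenvalue
on a connected mesh; only A = D + τS is strictly SPD, and only A is
handed to CG. These identities double as the package's conservation
checks: 1ᵀ(D+τS) = 1ᵀD means the diffusion step conserves total mass
1ᵀD·field exactly up to solver tolerance — *provided the clamp does not
fire*. Clamping negative undershoots (e.g. from discontinuous initial
data) adds mass; conservation tests therefore ride on a strictly positive
baseline state where the clamp is inert.

## Time stepping

Operator splitting with τ = 0.01 by default: explicit-Euler reaction
(pointwise, vectorized) then implicit-Euler diffusion (unconditionally
stable). The reverse order is available behind a config flag
(`order: diffusion_first`); the two differ at O(τ²) per step and the
default applies the reaction first. First-order accuracy in τ is verified
against an adaptive RK integration of the well-mixed kinetics.

## Linear solver

Hestenes-Stiefel conjugate gradient built strictly from three primitives:

* `spmv` — sparse matrix-vector product over stored nonzeros (CSR);
* `axpy` — X + λY;
* `tree_dot` — dot product with a blocked stride-doubling pairwise
  reduction (block size 1024 by default). The reduction order is fixed, so
  results are bit-identical across runs; this is an ordering contract, not
  a parallelism requirement, and arbitrary vector lengths are handled by
  skipping out-of-range partners.

Stopping rule: relative residual ‖b − Ax‖₂/‖b‖₂ ≤ rtol (default 0.001, the
conventional reading of a "relative residual" threshold; relative-to-initial
is available via `residual_reference: initial`). The residual is tracked by
recurrence; on claimed convergence the true residual is recomputed, and the
iteration restarts from it if the recurrence had drifted. A zero right-hand
side short-circuits to x = 0; pᵀAp ≤ 0 raises (the operator is not SPD);
hitting `max_iter` (default: the dimension m) is flagged in the report, not
raised — the simulation driver is the one that aborts, with step context.

Each diffusion solve is warm-started from the current field unless
disabled. Since consecutive states differ by O(τ), warm-started solves
typically converge in 0–2 iterations once the dynamics settle, versus ~7
cold — this dominates the observed mean iteration counts. No
preconditioner is used.

**Condition-number estimate.** κ̂ = max_v‖Av‖ · max_v‖A⁻¹v‖ over seeded
random unit-sphere probes (default 100), with A⁻¹v computed by CG at rtol
1e−10. Both factors are maxima over finitely many probes, so κ̂ ≤ κ always;
it is exact on the identity and approaches κ from below as probes grow.

## Synthetic data and what the tests show

The maze generator emulates the geometric motifs of microfluidic reactors
— straight corridors, right-angle corners, junctions, cul-de-sacs — with
axis-aligned walls on a pixel lattice. It does not emulate curved or
anti-aliased boundaries, braided (loopy) mazes, or fabrication noise, so
passing tests demonstrate correct physics on rectilinear geometries only.

Fixture sizes were chosen so each phenomenology check runs in seconds to
minutes on one CPU while the wave fully develops:

* straight corridor 40×4 px at s = 5 (4 221 nodes, 5 000 steps):
  first-passage times are non-decreasing along the corridor and no node's
  prey arrival precedes all of its neighbours' by more than one snapshot
  stride (no spontaneous generation);
* T-junction (28-px bar, 12-px stem, s = 5): both arm tips are reached —
  the wave splits;
* dead-end corridor 8×4 px at s = 12 (4 753 nodes, 6 500 steps): prey at
  the tip exceeds 0.1 and then falls below 1e−3 — cul-de-sac extinction.
  The longer horizon gives the predator time to finish the extinction
  after cornering the prey;
* refinement check: one 4×4-cell maze at s = 1, 2, 4, probe arrivals
  compared between the two finest levels (<5% deviation asserted; the
  coarsest level's deviation is recorded but not bounded — coarse meshes
  are expected to distort the dynamics).

## Numerical choices

* Mesh areas are accumulated with compensated summation; "area equals
  open-pixel count" holds to 1e−12 relative at any subdivision.
* Degenerate (zero-area) or clockwise triangles are rejected at element
  level and at assembly.
* The symmetric matrix wrapper enforces symmetry to 1e−12 relative on
  construction; file readers refuse non-symmetric content unless the
  caller explicitly opts into symmetrization.
* Node→pixel attribution for zone initialization uses floor with clipping
  at the upper boundary, so a one-pixel bottom strip selects exactly the
  bottom row of nodes.
* ε is subtracted unconditionally and the clamp restores exact zeros, so
  the all-zero state is an exact fixed point of the full step.

## Known limitations

* Uniform structured meshing only; no local refinement near re-entrant
  corners, no unstructured or graded meshes (though externally produced
  meshes can be imported from the plain-text format).
* Single fixed chemistry (the predator-prey pair); the reaction step is a
  generic two-field pointwise map internally, but no other network is
  shipped or tested.
* No advection, no adaptive time stepping, no higher-order (Strang)
  splitting; accuracy in time is first order.
* The condition-number estimator inherits the downward bias of random
  probing; on large matrices it can undershoot substantially at the
  default probe count.
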