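# Methods

## The model

`vasrem` simulates flow-driven remodelling of an embryonic capillary
plexus as a two-phase system of self-propelled particles. The tissue is
split by a binary mask into a vascular phase (endothelial agents inside
the lumen) and an avascular phase (the inter-vessel tissue). Both phases
are discretized into circular agents of diameter r_e = 7 um packed on a
triangular lattice at pitch r_e, so interior agents start at their
equilibrium separation.

Each 5-minute step (dt = 1/12 h) updates every agent's heading theta_i
synchronously as the argument of a weighted vector sum, plus white noise
nu * xi with xi ~ U[-pi, pi]:

* **Alignment (alpha).** Vascular agents prefer to migrate anti-parallel
  to the local flow; the alpha term sums the preferred directions of the
  agent and its vascular neighbours (Vicsek-style, self included — an
  isolated agent must still align against flow).
* **Body force (beta, kappa, beta_av, kappa_av).** A Lennard-Jones-type
  attraction/repulsion profile: capped repulsion below the repulsion
  distance, a linear restoring branch about the equilibrium separation,
  unit attraction out to the cutoff (distances r_c = 5 < r_e = 7 <
  r_a = 9 < r_o = 11 um for standard circles). For elongated agents the
  profile is evaluated three times per pair — from the neighbour's centre
  and from each focus — with equilibrium distances built from the two
  boundary extents along the connecting line and the other distances
  scaled by the circular ratios. With equal semi-axes the three
  contributions coincide, giving exactly 3x the circular force; the sum
  is therefore divided by 3 before weighting so beta remains commensurate
  with the circular-force convention (toggleable via
  `normalize_ellipse_force`).
* **Shear gradient (zeta).** Sum of (tau_j - tau_i) e_ij over vascular
  neighbours; points up-gradient in a linear field.
* **Remodelling force (omega, omega_av).** Crowded pairs (closer than the
  pairwise equilibrium) push the agent toward the nearest vessel wall;
  sparse pairs (between equilibrium and cutoff) pull it toward the vessel
  centreline (vascular) or away from the wall (avascular), with magnitude
  |r_ij - r_e|. Wall and centreline directions come from Euclidean
  distance transforms of the current mask and its skeleton, refreshed
  every 12 steps (1 h) from the rasterized agent state — the geometry
  changes slowly at these speeds.

Positions then advance by X <- X + V dt (cos theta, sin theta). Vascular
speed follows the bell-shaped shear response
V(tau) = V_max (tau/tau_max) exp(1 - tau/tau_max), a two-parameter
unimodal curve that is zero at zero shear and exactly V_max at tau_max
(defaults V_max = 12 um/h, tau_max = 0.033 Pa). Avascular agents move at
the fixed speed V_av = 8.4 um/h, but only while their net force vector is
non-zero (threshold 1e-6), so force equilibria are true fixed points.
After the move, any pair closer than its pairwise repulsion distance is
separated back to it (a hard overlap guard replacing the profile's
unbounded repulsion, which is capped at 10); agents leaving the raster
are clamped to its edge, a known edge artefact of the missing boundary
constraints.

**Elongation.** Vascular agents elongate additively along the local flow
axis: a(k) = (1 + 0.003125 k) * r_e/2 after k steps, b fixed at r_e/2,
reaching an aspect ratio of exactly 1.3 after 96 steps (8 h).

**Avascular growth.** Each cluster (connected component at seeding)
expands about its centre of mass: distances to the centroid and the
agents' radii grow linearly at 0.042 per hour of their initial values,
i.e. +78.5% cluster area over 8 h. The printed per-step reading of this
rate (0.042 x 96 steps) would contradict the 78.5%-in-8-h value, so the
per-hour reading is the default; the per-step variant is available as
`delta_av_per_step`. Whether radii grow relative to initial or current
values is equally ambiguous; linear-in-time growth of the initial value
is implemented.

Update order per step: (1) cluster centroids, (2) expansion + elongation,
(3) headings (synchronous), (4) moves, (5) overlap resolution. The order
is a package choice; no ordering is canonical for this model. Agents keep
their phase for the whole run (no birth, death or phase flips): the mask
is re-derived from the agents, never the reverse. When the heading vector
vanishes, the previous heading is kept (continuity; no NaN) and the noise
still applies on top.

**Baseline modes.** `gregoire` uses alignment and the vascular body force
only, with circular agents and a static avascular phase (the classic
cohesive-flocking model, driven here by shear-dependent speeds);
`random` draws each vascular heading uniformly every step while keeping
shear-dependent speeds. Both serve as comparison baselines for model
assessment.

## Synthetic geometries and analytic flow

Real inputs to such a model are a segmented vessel mask plus
velocimetry/CFD fields. This package instead generates templates —
straight channel, Y-bifurcation and honeycomb plexus — and assigns each
vessel segment a plane-Poiseuille profile: centreline velocity
1.5 U_mean, zero at the walls, wall shear tau_w = 6 mu U_mean / w.
Segment mean speeds come from a resistor-network solve (conductance
w^3 / 12 mu L per segment, inlet flux U_in * w per inlet terminal,
outlet pressure 0), so mass is conserved at junctions to solver precision
(< 1e-6 relative, typically ~1e-15). The honeycomb network is the dual
of the triangular hexagon-centre lattice, built analytically.

Interior shear is the wall value of the nearest segment — for a straight
segment both facing walls carry the same shear, so the cross-lumen
interpolation is constant. For user-supplied masks,
`interpolate_wall_shear` casts rays perpendicular to the local flow
direction, finds the two facing wall contacts (bisected to the pixel
interface) and combines their shear values with inverse-distance weights;
the result is always a convex combination of the two wall values, and an
on-wall query returns that wall's value.

Defaults are arbitrary but physiologic: viscosity 3 mPa.s, inlet mean
speed 500 um/s, pixel size 1 um/px (an agent spans 7 px), honeycomb
vessel width 25 um. The generator does not emulate pulsatile flow,
non-Newtonian rheology, 3-D lumens, image noise, segmentation errors or
flow re-equilibration as the geometry changes — passing tests show the
model machinery behaves as specified on clean planar geometries, not that
it reproduces any particular in vivo time-lapse. Simulations are limited
to a 4-h horizon for the same reason the method itself is: beyond it the
static flow field is no longer a good approximation.

## Evaluation pipeline

A final agent state is scored against an observed mask by: rasterizing
the vascular ellipses (pixel-centre inclusion), morphological closing
with a disk of radius 25% of the current semi-major axis (≈2 px at these
resolutions; fills the spurious holes left by rigid agents while
restoring real holes), isotropic scaling about the centroid (default
1.11, compensating overall growth the model does not simulate; set to 1.0
for synthetic benchmarks where both masks come from the same generator),
then rigid registration and finally the boundary Hausdorff distance (in
um and px — sources differ on the unit convention, so both are reported)
and the Dice coefficient.

Registration maximizes Dice (the objective is a package choice; a
Hausdorff re-ranking option exists): a coarse sweep over rotations
(±10° at 0.5°, refined to 0.1°) scores each angle by its best
FFT-correlation translation within ±20 px. The identity transform is
always in the search set, so registration never scores below the
unregistered overlay; exact ties prefer the smallest rotation.

## Calibration

`grid_search` exhaustively evaluates a Cartesian grid, each cell averaged
over replicate seeds and evaluation cases (mean objective by default,
minimax optional), with failed cells recorded rather than aborting. The
three staged preset grids cover the speed curve (V_max 6-14 um/h,
tau_max 0.02-0.5 Pa), the directional weights (alpha, zeta 0-100) and the
force weights (beta, kappa, omega 0-1000); step sizes within those ranges
are package defaults, as is the 3-seed replication. Avascular weights are
fixed at their defaults (100, 10, 10) and excluded from the search.
`sensitivity_analysis` perturbs each searched parameter one at a time by
relative fractions, switching to absolute increments (10, 20, 30, 40) for
a parameter whose optimum is zero.

Parameter recovery is exercised on synthetic time-lapses from the
honeycomb template (~1800 agents, 4 h), where heterogeneous shear makes
the outcome genuinely sensitive to the speed curve; on a straight channel
a speed change is mostly a rigid translation and registration would
absorb it.

## Numerical choices and steady states

* Repulsion cap 10 (dimensionless) plus the hard overlap guard keeps
  forces finite at dt = 5 min; the cap is configurable.
* The piecewise force is evaluated with half-open branches; the printed
  profile's 1/4 -> 1 discontinuity at r_a is preserved.
* Focal equilibrium distances use exact ray-ellipse intersections from
  each focus, which reduce to the circular case as the foci collapse.
* Fixed-speed stepping orbits an equilibrium rather than converging to
  it, so steady states (e.g. the two-agent equilibrium separation) are
  computed by `relax`: the model's own update iterated with the time-step
  halved whenever a displacement reverses, stopping when the largest
  per-step displacement drops below 1e-4 um.
* All randomness flows through one seeded generator per run; identical
  inputs, parameters and seed give bit-identical trajectories.

## Problem sizes

The shipped benchmarks use a 300 x 260 um honeycomb (pitch 100 um, width
25 um, ~800 vascular + ~1000 avascular agents) over 4 h, ten replicate
seeds for the baseline comparison, and a 4 x 4 recovery grid with five
synthetic time-lapses — sizes chosen so the full suite runs on a laptop
in minutes while still exercising every mechanism at realistic densities.

## Known limitations

* No proliferation, apoptosis or phase conversion; density changes come
  only from elongation and migration.
* No sprouting angiogenesis: the model cannot create new vessels, only
  reshape existing ones.
* The flow field is static over the simulated window.
* Strictly 2-D; the fluid-solid boundary is a raster mask, not a
  mechanical interface.
* Cluster labels are fixed at seeding; clusters that merge geometrically
  still expand about separate centroids.
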