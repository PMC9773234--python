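# Methods

`granulocell` simulates an adherent cell spreading on a free-packed bed of
microspheres and asks the single question the in-vitro system poses: does
the cell's own contractility rip its adhesions off the granular substrate
(anoikis-prone fate), or does the substrate hold (survival-prone fate)?
The model couples three ingredients: a discrete-element granular bed, a
spring-network cell, and minimal integrin/talin adhesion kinetics.

## Dimensionless units

Lengths are measured in mean microparticle diameters `d`, gravity is 1, and
the mass unit is the *effective* (buoyancy-reduced) mass of a mean-diameter
polystyrene particle in water.  A mean particle therefore has weight 1.
The time unit is `sqrt(d_phys / g_phys)`; for `d_phys = 32 um` one
dimensionless time is 1.8 ms.  All gravitational forces use effective
masses (the medium enters only through buoyancy: no drag, no hydrodynamics)
and the same values serve as inertial masses — the dynamics of interest is
quasi-static, so inertial detail is immaterial.

The force calibration is experimental: the maximum traction force of a
human adipose-derived stem cell, ~200 pN, equals the buoyant weight of an
82 um polystyrene sphere in water.  Scaled to a cell of diameter `L_i`,
the maximum cell force is the buoyant weight of a sphere `82/32 · L_i` in
diameter — dimensionlessly `(2.5625 · L_i)^3`.

## Granular bed (DEM)

Particles (5% uniform size dispersion) are placed randomly without overlap
and dropped under gravity in a box periodic in x/y with a floor plane at
z = 1; the default box is `(20 d)^3` and the particle count is
`layers × floor(L_x/d) × floor(L_y/d)`.  Contacts are linear normal
springs with a stiff loading branch `Y_u = 5e4·d_pair` while a pair
approaches and a soft unloading branch `Y_l = 5e3·d_pair` while it
separates (`d_pair` = pair mean diameter; a particle's own diameter against
the floor).  This two-branch law dissipates every collision with
restitution `sqrt(Y_l/Y_u) ≈ 0.316` and keeps rest overlaps below 1%.
There is no rotation, friction, or cohesion.  The bed is relaxed when the
mean kinetic energy per particle falls below `2e-3`; the settled height is
close to the target layer count.

Numerical choices: 4th-order (5-value) Gear predictor–corrector with
`alpha_0 = 19/90` (velocity-dependent forces), time step `5e-5`;
cell-binned Verlet neighbour lists rebuilt when any body moves half a skin
(0.3 particle radii); initial placement fills only the lower part of the
box (packing fraction ~0.15) so the free fall is short — the settled
packing is unaffected.  The Gear state is warm-started from the initial
forces so constant-force trajectories carry no half-step velocity offset.

Density variants rescale particle masses after settling: relative density
1 is polystyrene, 2 is glass, and infinity is the sintered condition, in
which every particle is simply immobile.

## Cell model

The cell is a planar sheet of spherical elements (diameter `L_i/3`, same
material density as the particles) joined by Kelvin–Voigt springs with
elastic constant `k_s = 6.25·L_i²` and damping `c_s = 6.25e-2·L_i²`.  It
starts as 7 elements in a hexagon whose smallest enclosing circle is
`L_i`; two further precomputed rings (12 and 24 elements, two children per
periphery element) bring the fully spread diameter to `L_f = 2·L_i`.  Ring
radii interpolate the enclosing diameter linearly between `L_i` and
`2·L_i`.  Inactive rings idle at 1e-3 of their mass, tethered to the
template frame that translates with the centre element, and do not touch
anything until activated.

Spreading alternates stretch and contraction.  A stretch phase activates
the next ring at template positions (children of terminal directions stay
off; new elements are lifted just clear of the bed so the protrusion
drapes from above), resets every spring's natural length to its template
value, and relaxes the assembly to rest.  A contraction phase ramps every
natural length linearly to zero over `contraction_steps` (default 5e4
steps) while the adhesion kinetics run every step.

Elements collide with particles and the floor exactly like particles do.
Element–element collisions apply only beyond graph distance 2 in the
spring network (the MD 1-2/1-3 exclusion): the printed outer-ring spacing
(0.435·L_i) is below one element diameter, so nearer neighbours must be
free to overlap, while the exclusion of only near neighbours still
prevents the sheet from folding through itself.

"Rest" after a stretch cannot be detected as a vanishing net force: the
two-branch contact law flips stiffness with the sign of the approach
velocity, so resting contacts chatter at machine scale and the
instantaneous net force never vanishes.  Relaxation instead stops when the
mean active-element speed drops below 5e-3 (dimensionless), with a weak
global velocity quench (rate 2 per unit time) to shorten the overdamped
approach; the quench does not move the static equilibria.

## Adhesion kinetics

Three mechanisms, all deterministic:

* **Binding** is instantaneous on contact: each active, non-terminal
  element binds its deepest-overlapping particle (one bond per element)
  with a binding spring anchored at the contact point.  The elastic
  constant is the maximum cell force divided by `2.5e-5·L_i`, i.e. the
  force threshold is reached at a stretch of 0.0025% of `L_i`; the damping
  constant is the maximum cell force divided by `1.25e-2·L_i`.
* **Reinforcement** (talin unfolding, vinculin locking) fires the instant
  a binding spring's elastic force reaches the maximum cell force; the
  element and its particle are frozen in place and the bond can never
  break.
* **Detachment** encodes the 2–4 s integrin lifetime geometrically: a
  bond breaks when its element moves more than 4% of `L_i` closer to the
  position the centre element had at binding time.  The broken direction
  becomes terminal — the cell stops spreading there.  The bond population
  also turns over on the lifetime timescale: during contraction, anchors
  and slip budgets renew every interval in which the schedule contracts
  4% of `L_i` (about 1/20 of a contraction phase).  Slow creep under
  sub-threshold load is therefore forgiven, and only elements dragged
  along with the contraction — light particles in tow — exceed the budget
  and unbind.  With immobile (sintered) particles a bound element cannot
  move, so detachment never fires, matching the observed survival on
  sintered beds at every particle size.

The binding and structural dashpots are orders of magnitude stiffer than
an explicit integrator tolerates (`c·dt/m` up to ~1), so their viscous
parts are integrated exactly: once per step the relative velocity of each
pair decays by `exp(-c·dt/mu)`, split by mass (momentum conserving,
unconditionally stable, exact for a pure dashpot).  Elastic forces always
go through the Gear corrector.  The time step is additionally capped so
the stiffest multi-bond elastic mode satisfies `omega·dt <= 0.22`
(operative only for small cells, `L_i/d` below ~0.7).

## Fate statistic and sweeps

The **volume ratio** is the union-of-spheres volume of the final active
elements divided by that of a reference cell replayed through the same
schedule with contraction (and adhesion kinetics) disabled — the
no-contraction upper bound.  Volumes are estimated by scrambled-Sobol
sampling of the bounding box (2^16 points, well under 1% relative error);
the two runs share the drop and first stretch, which are identical up to
the first contraction.  The ratio is ~1 when adhesions hold and falls
toward the contracted minimum when spreading halts and the sheet compacts.

A sweep runs `n_drop_positions × n_bed_configs` replicates per
(aspect ratio `L_i/d`, relative density, bed layers) condition — the full
protocol is a 4×4 drop grid × 10 beds (160 samples) — and reports mean ±
standard error.  Beds are settled once per (layers, seed) and shared
across ratios and densities; every random stream derives from one master
seed through a counter-based splitting rule, so any sample is reproducible
in isolation.

## Problem sizes

The library defaults are the full study conditions: `(20 d)^3` box,
3 bed layers (1200 particles), 16 drop positions × 10 beds.  The test
suite exercises the same physics at sizes chosen for a desk run: a
`(10 d)^3` box (300 particles) for cell-fate sweeps with 4 drop positions
× 2 beds per condition, and miniature fixtures (2–25 particles) for unit
tests.  The fate statistic depends on the local bed neighbourhood, not the
box, once the box comfortably exceeds the spread cell (≥ 2.5× here).

## Known limitations

* No tangential contact forces: beds are frictionless, so granular yield
  thresholds are lower than for real (frictional) microsphere packings.
* No fluid mechanics beyond buoyancy; no active migration, division, or
  cell–cell contact.
* Adhesion kinetics are deterministic caricatures — single force
  threshold, single slip budget — rather than stochastic catch/slip bond
  chemistry.
* The synthetic beds emulate geometry and weight of the experimental
  microspheres but none of their surface chemistry; agreement of fate
  trends with experiments therefore tests the mechanical hypothesis only.
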